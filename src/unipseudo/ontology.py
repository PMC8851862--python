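"""Minimal GO ontology (OBO subset) and gene annotation (GAF subset) handling,
plus keyword-driven functional-group assignment.

Only the fields the enrichment analysis needs are parsed: term id, name,
namespace and is_a parents from OBO; gene symbol (column 2) and GO id
(column 5) from GAF.  Ancestor closure follows is_a edges only.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class GoTerm:
    term_id: str
    name: str = ""
    namespace: str = ""
    is_a: list[str] = field(default_factory=list)
    obsolete: bool = False


@dataclass
class Ontology:
    terms: dict[str, GoTerm] = field(default_factory=dict)

    def ancestors(self, term_id: str) -> set[str]:
        """is_a closure including the term itself."""
        seen: set[str] = set()
        stack = [term_id]
        while stack:
            cur = stack.pop()
            if cur in seen or cur not in self.terms:
                continue
            seen.add(cur)
            stack.extend(self.terms[cur].is_a)
        return seen


def parse_obo(path_or_text: str | Path) -> Ontology:
    text = (
        Path(path_or_text).read_text()
        if isinstance(path_or_text, Path) or "\n" not in str(path_or_text)
        else str(path_or_text)
    )
    onto = Ontology()
    term: GoTerm | None = None
    in_term = False
    for line in text.splitlines():
        line = line.strip()
        if line == "[Term]":
            in_term = True
            term = None
            continue
        if line.startswith("["):
            in_term = False
            continue
        if not in_term or not line:
            continue
        key, _, value = line.partition(": ")
        if key == "id":
            term = GoTerm(term_id=value)
            onto.terms[value] = term
        elif term is None:
            continue
        elif key == "name":
            term.name = value
        elif key == "namespace":
            term.namespace = value
        elif key == "is_a":
            term.is_a.append(value.split("!")[0].strip())
        elif key == "is_obsolete" and value == "true":
            term.obsolete = True
    return onto


def parse_gaf(path_or_text: str | Path) -> dict[str, set[str]]:
    """gene symbol -> set of GO ids (GAF 2.x columns 2 and 5)."""
    text = (
        Path(path_or_text).read_text()
        if isinstance(path_or_text, Path) or "\n" not in str(path_or_text)
        else str(path_or_text)
    )
    out: dict[str, set[str]] = {}
    for line in text.splitlines():
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 5:
            continue
        out.setdefault(cols[1], set()).add(cols[4])
    return out


@dataclass
class FunctionalGroup:
    name: str
    keywords: tuple[str, ...]
    term_ids: set[str] = field(default_factory=set)
    members: set[str] = field(default_factory=set)


def parse_keyword_map(path_or_text: str | Path) -> dict[str, tuple[str, ...]]:
    """TSV: group name <tab> comma-separated keywords."""
    text = (
        Path(path_or_text).read_text()
        if isinstance(path_or_text, Path) or "\n" not in str(path_or_text)
        else str(path_or_text)
    )
    groups: dict[str, tuple[str, ...]] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, _, kws = line.partition("\t")
        groups[name.strip()] = tuple(k.strip().lower() for k in kws.split(",") if k.strip())
    return groups


def assign_functional_groups(
    gene_go: dict[str, set[str]],
    ontology: Ontology,
    keyword_map: dict[str, tuple[str, ...]],
) -> list[FunctionalGroup]:
    """A gene joins a group iff any of its GO terms — ancestors via is_a
    included — has a name matching one of the group's keywords."""
    groups = [FunctionalGroup(name, kws) for name, kws in sorted(keyword_map.items())]
    for g in groups:
        for term in ontology.terms.values():
            if any(kw in term.name.lower() for kw in g.keywords):
                g.term_ids.add(term.term_id)
    for gene, term_ids in sorted(gene_go.items()):
        closure: set[str] = set()
        for tid in term_ids:
            if tid not in ontology.terms:
                warnings.warn(f"unknown GO id {tid} for gene {gene}; skipped")
                continue
            closure |= ontology.ancestors(tid)
        for g in groups:
            if closure & g.term_ids:
                g.members.add(gene)
    return groups
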