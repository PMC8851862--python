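"""Codon sequence simulation under a Muse–Gaut-style substitution process.

Only single-nucleotide codon changes are allowed; each change is weighted by
a transition/transversion bias kappa and, when non-synonymous, by omega.
Branch lengths are interpreted as expected substitutions per codon site
under that branch's omega (rates are renormalized per branch class).
The foreground branch evolves with omega = omega_bg ** k.
"""
from __future__ import annotations

import io

import dendropy
import numpy as np

from ..genetics import BASES, SENSE_CODONS, STOP_CODONS, is_transition, translate


class ForegroundError(ValueError):
    """Tree lacks (or over-specifies) the foreground mark."""


def _neighbor_table(kappa: float, omega: float):
    """codon -> (list of target codons, cumulative rate array, total rate)."""
    table = {}
    rates_sum = 0.0
    for codon in SENSE_CODONS:
        targets: list[str] = []
        rates: list[float] = []
        aa = translate(codon)
        for j in range(3):
            for b in BASES:
                if b == codon[j]:
                    continue
                cand = codon[:j] + b + codon[j + 1 :]
                if cand in STOP_CODONS:
                    continue
                r = kappa if is_transition(codon[j], b) else 1.0
                if translate(cand) != aa:
                    r *= omega
                targets.append(cand)
                rates.append(r)
        arr = np.array(rates)
        table[codon] = (targets, arr, float(arr.sum()))
        rates_sum += float(arr.sum())
    # normalize: mean total rate per codon == 3 (one per site)
    scale = rates_sum / len(SENSE_CODONS) / 3.0
    return {c: (t, r / scale, s / scale) for c, (t, r, s) in table.items()}


def _evolve_branch(
    rng: np.random.Generator, seq: list[str], t: float, table
) -> list[str]:
    out = list(seq)
    for i, codon in enumerate(out):
        time = 0.0
        cur = codon
        while True:
            targets, rates, total = table[cur]
            if total <= 0:
                break
            time += rng.exponential(1.0 / total)
            if time >= t:
                break
            cur = targets[rng.choice(len(targets), p=rates / total)]
        out[i] = cur
    return out


def parse_marked_tree(
    newick: str, foreground: str | None = None
) -> tuple[dendropy.Tree, dendropy.Node]:
    """Parse newick; locate the single foreground branch.

    The foreground is a leaf whose label ends in ``#1`` (PAML style), or the
    leaf named by ``foreground``.
    """
    cleaned = newick
    marked_taxon = None
    if foreground is None:
        import re

        m = re.findall(r"([\w.\-|]+)\s*#1", newick)
        if len(m) != 1:
            raise ForegroundError(
                f"expected exactly one '#1'-marked branch, found {len(m)}"
            )
        marked_taxon = m[0]
        cleaned = newick.replace("#1", "")
    tree = dendropy.Tree.get(data=cleaned, schema="newick")
    target = foreground if foreground is not None else marked_taxon
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label.replace(" ", "_") == target.replace(" ", "_"):
            return tree, leaf
    raise ForegroundError(f"foreground taxon {target!r} not found in tree")


def simulate_codon_sequences(
    tree: str,
    omega_bg: float,
    k: float,
    kappa: float = 2.0,
    n_codons: int = 300,
    seed: int = 0,
    foreground: str | None = None,
) -> dict[str, str]:
    """Evolve CDS along ``tree``; returns {taxon label: CDS string}.

    Background branches use omega_bg, the foreground branch omega_bg ** k.
    """
    if omega_bg <= 0:
        raise ValueError("omega_bg must be > 0")
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    t, fg_node = parse_marked_tree(tree, foreground)
    rng = np.random.default_rng(seed)
    omega_fg = omega_bg**k
    bg_table = _neighbor_table(kappa, omega_bg)
    fg_table = bg_table if omega_fg == omega_bg else _neighbor_table(kappa, omega_fg)

    root_seq = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    seqs: dict[str, str] = {}

    def recurse(node: dendropy.Node, seq: list[str]) -> None:
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            table = fg_table if child is fg_node else bg_table
            child_seq = _evolve_branch(rng, seq, bl, table)
            if child.is_leaf():
                seqs[child.taxon.label.replace(" ", "_")] = "".join(child_seq)
            else:
                recurse(child, child_seq)

    recurse(t.seed_node, root_seq)
    return seqs


def balanced_foreground_tree(
    n_taxa: int = 16, bg_length: float = 0.05, fg_length: float = 0.4
) -> str:
    """Balanced binary tree with taxon t1 marked foreground (#1)."""
    if n_taxa < 2 or n_taxa & (n_taxa - 1):
        raise ValueError("n_taxa must be a power of two >= 2")
    labels = [f"t{i + 1}" for i in range(n_taxa)]

    def build(lo: int, hi: int) -> str:
        if hi - lo == 1:
            name = labels[lo]
            bl = fg_length if name == "t1" else bg_length
            mark = "#1" if name == "t1" else ""
            return f"{name}{mark}:{bl}"
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):{bg_length}"

    return build(0, n_taxa) + ";"
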