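"""Foreground/background dN/dS estimation.

Ancestral codon states by per-site Fitch parsimony; synonymous and
non-synonymous substitutions and sites counted per branch with Nei–Gojobori
pathway counting; omega per branch class from Jukes–Cantor-corrected
proportions.  Per-column counts are kept so the bootstrap can resample codon
columns without re-running the reconstruction.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import dendropy
import numpy as np

from ..genetics import BASES, STOP_CODONS, translate
from .align import CodonAlignment


@lru_cache(maxsize=None)
def ng_sites(codon: str) -> tuple[float, float]:
    """(N_sites, S_sites) for one codon over its 9 single-nt neighbours.

    Changes to stop codons count as non-synonymous.
    """
    aa = translate(codon)
    n = s = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and translate(alt) == aa:
                syn += 1
        s += syn / 3.0
        n += (3 - syn) / 3.0
    return n, s


@lru_cache(maxsize=None)
def ng_substitutions(a: str, b: str) -> tuple[float, float]:
    """(non-syn, syn) substitution counts between two codons.

    Multi-step differences are averaged over all orderings of the single-nt
    path; paths through stop codons are skipped when any stop-free path
    exists.
    """
    if a == b:
        return 0.0, 0.0
    diff = [i for i in range(3) if a[i] != b[i]]
    paths = []
    for order in itertools.permutations(diff):
        cur = a
        nd = sd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != b:
                blocked = True
            if translate(nxt) == translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((blocked, nd, sd))
    open_paths = [p for p in paths if not p[0]] or paths
    nd = sum(p[1] for p in open_paths) / len(open_paths)
    sd = sum(p[2] for p in open_paths) / len(open_paths)
    return nd, sd


def _fitch_column(
    tree: dendropy.Tree, states: dict[str, str], prefer: str | None = None
) -> dict:
    """Fitch parsimony for one nucleotide site; returns node -> base.

    ``prefer`` breaks root-state ties (use the background-majority base so
    that ambiguous substitutions land on the foreground branch)."""
    sets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            base = states[node.taxon.label.replace(" ", "_")]
            sets[node] = {base} if base in "ACGT" else set("ACGT")
        else:
            child_sets = [sets[c] for c in node.child_nodes()]
            inter = set.intersection(*child_sets)
            sets[node] = inter if inter else set.union(*child_sets)
    assign: dict = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            root_set = sets[node]
            if prefer is not None and prefer in root_set:
                assign[node] = prefer
            else:
                assign[node] = min(root_set)
        else:
            p = assign[node.parent_node]
            assign[node] = p if p in sets[node] else min(sets[node])
    return assign


@dataclass
class ColumnStats:
    """Per-codon-column substitution/site counts, split by branch class.

    Arrays are (n_columns,); class 0 = background, 1 = foreground.
    """

    nd: np.ndarray  # (2, n)
    sd: np.ndarray
    n_sites: np.ndarray
    s_sites: np.ndarray


@dataclass
class OmegaEstimate:
    omega_fg: float | None
    omega_bg: float | None
    counts: dict[str, float] = field(default_factory=dict)
    columns: ColumnStats | None = None
    reason: str = ""


def _omega_from_counts(nd: float, sd: float, n_sites: float, s_sites: float) -> float | None:
    if sd <= 0 or s_sites <= 0 or n_sites <= 0:
        return None
    pn = nd / n_sites
    ps = sd / s_sites
    if pn >= 0.75 or ps >= 0.75:
        return None
    dn = -0.75 * math.log1p(-4.0 * pn / 3.0)
    ds = -0.75 * math.log1p(-4.0 * ps / 3.0)
    if ds <= 0:
        return None
    return dn / ds


def estimate_omega(
    aln: CodonAlignment,
    tree: str,
    foreground: str,
) -> OmegaEstimate:
    """Per-branch-class omega from parsimony ancestral states + NG counting.

    The foreground class is the terminal branch of ``foreground``; all other
    branches (outgroup included) are background.
    """
    t = dendropy.Tree.get(data=tree.replace("#1", ""), schema="newick")
    labels = {leaf.taxon.label.replace(" ", "_") for leaf in t.leaf_node_iter()}
    missing = set(aln.rows) - labels
    if missing:
        raise ValueError(f"taxa missing from tree: {sorted(missing)}")
    t.retain_taxa_with_labels(
        [l.taxon.label for l in t.leaf_node_iter()
         if l.taxon.label.replace(" ", "_") in aln.rows]
    )

    n_cols = aln.n_columns
    stats = ColumnStats(
        nd=np.zeros((2, n_cols)),
        sd=np.zeros((2, n_cols)),
        n_sites=np.zeros((2, n_cols)),
        s_sites=np.zeros((2, n_cols)),
    )
    edges = [
        (node.parent_node, node)
        for node in t.preorder_node_iter()
        if node.parent_node is not None
    ]

    for col in range(n_cols):
        codons = aln.column(col)
        assigns = []
        for site in range(3):
            states = {sp: c[site] for sp, c in codons.items()}
            bg = [b for sp, b in states.items() if sp != foreground and b in "ACGT"]
            prefer = max(sorted(set(bg)), key=bg.count) if bg else None
            assigns.append(_fitch_column(t, states, prefer))
        node_codon = {}
        for parent, node in edges:
            for nd_ in (parent, node):
                if nd_ not in node_codon:
                    node_codon[nd_] = "".join(a[nd_] for a in assigns)
        for parent, node in edges:
            cls = 1 if (
                node.is_leaf()
                and node.taxon.label.replace(" ", "_") == foreground
            ) else 0
            pc, cc = node_codon[parent], node_codon[node]
            nd_c, sd_c = ng_substitutions(pc, cc)
            pn_sites, ps_sites = ng_sites(pc) if pc not in STOP_CODONS else (3.0, 0.0)
            cn_sites, cs_sites = ng_sites(cc) if cc not in STOP_CODONS else (3.0, 0.0)
            stats.nd[cls, col] += nd_c
            stats.sd[cls, col] += sd_c
            stats.n_sites[cls, col] += (pn_sites + cn_sites) / 2.0
            stats.s_sites[cls, col] += (ps_sites + cs_sites) / 2.0

    totals = {
        "nd_bg": float(stats.nd[0].sum()),
        "sd_bg": float(stats.sd[0].sum()),
        "n_sites_bg": float(stats.n_sites[0].sum()),
        "s_sites_bg": float(stats.s_sites[0].sum()),
        "nd_fg": float(stats.nd[1].sum()),
        "sd_fg": float(stats.sd[1].sum()),
        "n_sites_fg": float(stats.n_sites[1].sum()),
        "s_sites_fg": float(stats.s_sites[1].sum()),
    }
    omega_bg = _omega_from_counts(
        totals["nd_bg"], totals["sd_bg"], totals["n_sites_bg"], totals["s_sites_bg"]
    )
    omega_fg = _omega_from_counts(
        totals["nd_fg"], totals["sd_fg"], totals["n_sites_fg"], totals["s_sites_fg"]
    )
    reason = ""
    if omega_bg is None or omega_fg is None:
        reason = "no_signal"
    return OmegaEstimate(
        omega_fg=omega_fg, omega_bg=omega_bg, counts=totals, columns=stats, reason=reason
    )
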