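"""Selection-intensity k and the relaxed-selection retention gate.

Under the relaxation parameterization omega_fg = omega_bg ** k, so
k = ln(omega_fg) / ln(omega_bg).  The gate retains a gene iff
omega_fg > omega_bg and k < 1; the bootstrap p (probability of k >= 1 under
codon-column resampling) is advisory only and never part of the gate.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .omega import OmegaEstimate, _omega_from_counts


@dataclass
class RelaxationResult:
    gene_id: str
    omega_fg: float | None
    omega_bg: float | None
    k: float | None
    p_relax: float | None  # bootstrap P(k >= 1)
    retained: bool
    reason: str = ""


def selection_intensity(omega_fg: float, omega_bg: float) -> float | None:
    """k = ln(omega_fg)/ln(omega_bg); None when the background is >= 1
    (the exponent is then undefined under this parameterization)."""
    if omega_bg <= 0 or omega_fg <= 0:
        return None
    if omega_bg >= 1.0:
        return None
    return math.log(omega_fg) / math.log(omega_bg)


def gate(omega_fg: float | None, omega_bg: float | None, k: float | None) -> bool:
    """Pure retention decision: omega_fg > omega_bg and k < 1.

    When k is undefined because omega_bg >= 1, fall back to the
    omega_fg > omega_bg criterion alone.
    """
    if omega_fg is None or omega_bg is None:
        return False
    if k is None:
        return omega_fg > omega_bg
    return omega_fg > omega_bg and k < 1.0


def relaxation_test(
    estimate: OmegaEstimate,
    gene_id: str = "",
    n_bootstrap: int = 200,
    seed: int = 0,
) -> RelaxationResult:
    """Gate decision plus a nonparametric codon-column bootstrap p for k >= 1."""
    omega_fg, omega_bg = estimate.omega_fg, estimate.omega_bg
    if omega_fg is None or omega_bg is None:
        return RelaxationResult(
            gene_id, omega_fg, omega_bg, None, None, False,
            reason=estimate.reason or "no_signal",
        )
    k = selection_intensity(omega_fg, omega_bg)
    retained = gate(omega_fg, omega_bg, k)
    reason = "k_undefined_omega_bg_ge_1" if k is None else ""

    p_relax = None
    cols = estimate.columns
    if cols is not None and n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        n = cols.nd.shape[1]
        hits = 0
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            ob = _omega_from_counts(
                cols.nd[0, idx].sum(), cols.sd[0, idx].sum(),
                cols.n_sites[0, idx].sum(), cols.s_sites[0, idx].sum(),
            )
            of = _omega_from_counts(
                cols.nd[1, idx].sum(), cols.sd[1, idx].sum(),
                cols.n_sites[1, idx].sum(), cols.s_sites[1, idx].sum(),
            )
            if ob is None or of is None or ob >= 1.0 or ob <= 0.0:
                hits += 1  # k undefined counts against relaxation
                continue
            if of <= 0.0:
                hits += 1  # omega_fg of 0 means intensified, k -> +inf
                continue
            kb = math.log(of) / math.log(ob)
            if kb >= 1.0:
                hits += 1
        p_relax = hits / n_bootstrap
    return RelaxationResult(gene_id, omega_fg, omega_bg, k, p_relax, retained, reason)
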