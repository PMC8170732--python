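"""Supervised ancestry proportions and the taurine-admixture gate.

Given fixed reference allele frequencies ``f_jk`` for K candidate ancestral
populations, each sample's ancestry vector q (on the simplex) maximizes the
binomial log-likelihood of its dosages g_j:

    L(q) = sum_j [ g_j log(sum_k q_k f_jk) + (2 - g_j) log(sum_k q_k (1 - f_jk)) ].

L is concave in q for fixed f, so the multiplicative EM update from a
uniform start converges to the global optimum; the likelihood is checked to
be non-decreasing every iteration.  Summing q over the taurine-labeled
reference columns gives each animal's total taurine ancestry; animals whose
total exceeds the gate threshold (1% by default) are classified admixed and
excluded from the downstream diversity and Ne analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import GenotypePanel, ZebuPopError, _MISSING, allele_frequencies

_F_CLAMP = 1e-4
TAURINE_GATE = 0.01  # "> 1% taurine ancestry" exclusion rule


@dataclass
class ReferencePanelFreqs:
    """Marker-aligned reference frequencies, one column per population."""

    freq: np.ndarray  # (n_markers, K)
    populations: list
    n_per_population: list
    taurine: np.ndarray  # boolean mask over populations

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=np.float64)
        if self.freq.ndim != 2 or self.freq.shape[1] != len(self.populations):
            raise ZebuPopError("reference frequency matrix shape mismatch")
        if np.nanmin(self.freq) < 0 or np.nanmax(self.freq) > 1:
            raise ZebuPopError("reference frequencies outside [0, 1]")
        self.taurine = np.asarray(self.taurine, dtype=bool)

    @classmethod
    def from_panel(cls, panel: GenotypePanel, taurine_labels: set) -> "ReferencePanelFreqs":
        tab = allele_frequencies(panel, "by_breed")
        pops = tab.groups
        return cls(
            freq=tab.freq.T,
            populations=pops,
            n_per_population=[len(panel.samples_in_breed(b)) for b in pops],
            taurine=np.array([b in taurine_labels for b in pops]),
        )


@dataclass
class AncestryProportions:
    sample_id: str
    q: np.ndarray
    populations: list
    log_likelihood: float
    converged: bool
    n_iter: int

    def taurine_sum(self, taurine_mask: np.ndarray) -> float:
        """Total ancestry attributed to the taurine-labeled reference columns."""
        return float(self.q[np.asarray(taurine_mask, dtype=bool)].sum())


def supervised_proportions(
    genotypes: np.ndarray,
    refs: ReferencePanelFreqs,
    tol: float = 1e-6,
    max_iter: int = 5000,
    sample_id: str = "",
    check_monotone: bool = False,
) -> AncestryProportions:
    """EM estimate of one sample's ancestry proportions over the references.

    ``genotypes`` is the sample's dosage vector aligned to ``refs``; missing
    calls (NaN or the internal missing code) are skipped.  Deterministic:
    always starts from the uniform vector.  Convergence is declared on the
    maximum per-component change of q falling below ``tol`` (the likelihood
    flattens long before boundary components finish their geometric decay,
    so a likelihood-based stop would freeze small admixture fractions at
    inflated values).
    """
    g = np.asarray(genotypes, dtype=np.float64)
    if g.shape[0] != refs.freq.shape[0]:
        raise ZebuPopError("genotype vector not aligned to reference markers")
    ok = ~np.isnan(g) & (g != _MISSING)
    g = g[ok]
    f = np.clip(refs.freq[ok, :], _F_CLAMP, 1.0 - _F_CLAMP)
    m, k = f.shape
    if m == 0 or not ((f > _F_CLAMP) & (f < 1 - _F_CLAMP)).any():
        raise ZebuPopError("no informative markers for ancestry estimation")
    if k == 1:
        return AncestryProportions(sample_id, np.array([1.0]), list(refs.populations), 0.0, True, 0)
    q = np.full(k, 1.0 / k)
    two_m = 2.0 * m

    def loglik(qv):
        d = f @ qv
        e = (1.0 - f) @ qv
        return float(np.sum(g * np.log(d) + (2.0 - g) * np.log(e)))

    ll = loglik(q)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d = f @ q
        e = (1.0 - f) @ q
        w = (g / d) @ f + ((2.0 - g) / e) @ (1.0 - f)
        q_new = q * w / two_m
        q_new = q_new / q_new.sum()  # guard drift from float rounding
        delta = float(np.max(np.abs(q_new - q)))
        q = q_new
        if check_monotone:
            new_ll = loglik(q)
            if new_ll < ll - 1e-8 * max(1.0, abs(ll)):
                raise AssertionError("EM likelihood decreased")
            ll = new_ll
        if delta < tol:
            converged = True
            break
    ll = loglik(q)
    return AncestryProportions(sample_id, q, list(refs.populations), ll, converged, it)


def panel_proportions(
    panel: GenotypePanel, refs: ReferencePanelFreqs, **kwargs
) -> pd.DataFrame:
    """Ancestry table for every sample in a panel (one row per sample)."""
    rows = []
    d = panel.dosages()
    for i, sid in enumerate(panel.sample_ids):
        res = supervised_proportions(d[i], refs, sample_id=sid, **kwargs)
        row = {"sample_id": sid, "breed": panel.breed_labels[i],
               "log_likelihood": res.log_likelihood, "converged": res.converged,
               "taurine_total": res.taurine_sum(refs.taurine)}
        row.update({f"q_{p}": v for p, v in zip(refs.populations, res.q)})
        rows.append(row)
    return pd.DataFrame(rows)


def classify_admixed(
    proportions: pd.DataFrame, threshold: float = TAURINE_GATE
) -> pd.DataFrame:
    """Apply the taurine gate: admixed iff taurine_total > threshold.

    Input must carry a ``taurine_total`` column (from :func:`panel_proportions`).
    Returns the table with a ``status`` column in {"pure", "admixed"}.
    """
    if "taurine_total" not in proportions.columns:
        raise ZebuPopError("no taurine-labeled ancestry column present")
    out = proportions.copy()
    out["status"] = np.where(out["taurine_total"] > threshold, "admixed", "pure")
    return out
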