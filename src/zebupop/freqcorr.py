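"""Allele-frequency correlations between breeds with sampling-error correction.

Observed Pearson correlations of per-breed allele frequencies understate the
correlation of the *true* frequencies because each estimate carries binomial
sampling error.  With V_p the variance of the pooled meta-population
frequencies and V_e1, V_e2 the mean per-breed error variances p(1-p)/(2n),
the expected correlation under identical true frequencies is

    R_exp = V_p / (V_p + V_e1 + V_e2),

and R_obs^2 / R_exp^2 estimates the proportion of true frequency variance in
one breed explained by the other.  A product-form attenuation
V_p / sqrt((V_p+V_e1)(V_p+V_e2)) is provided as a labeled alternative for
sensitivity analysis; the additive form is primary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import GenotypePanel, ZebuPopError, allele_frequencies

POOL_LABEL = "POOLED_ALL"


@dataclass
class FreqCorrResult:
    breed_a: str
    breed_b: str
    r_obs: float
    r_exp: float
    ratio: float
    n1: int
    n2: int
    vp: float
    ve1: float
    ve2: float
    maf_filter_used: bool


def observed_corr(freq_a: np.ndarray, freq_b: np.ndarray) -> float:
    """Pearson correlation of two allele-frequency vectors."""
    a = np.asarray(freq_a, dtype=np.float64)
    b = np.asarray(freq_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ZebuPopError("frequency vectors differ in length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        raise ZebuPopError("correlation undefined: fewer than 2 varying markers")
    return float(np.corrcoef(a, b)[0, 1])


def error_variance(p: np.ndarray, n: int) -> float:
    """Mean binomial sampling variance of a frequency estimate: mean p(1-p)/(2n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    p = np.asarray(p, dtype=np.float64)
    return float(np.nanmean(p * (1.0 - p)) / (2.0 * n))


def expected_corr(vp: float, ve1: float, ve2: float) -> float:
    """R_exp = Vp / (Vp + Ve1 + Ve2)."""
    if vp <= 0:
        raise ZebuPopError("Vp must be positive")
    if ve1 < 0 or ve2 < 0:
        raise ValueError("error variances must be non-negative")
    return vp / (vp + ve1 + ve2)


def expected_corr_product(vp: float, ve1: float, ve2: float) -> float:
    """Alternative product-form attenuation Vp / sqrt((Vp+Ve1)(Vp+Ve2))."""
    if vp <= 0:
        raise ZebuPopError("Vp must be positive")
    return vp / np.sqrt((vp + ve1) * (vp + ve2))


def variance_explained_ratio(r_obs: float, r_exp: float) -> float:
    """R_obs^2 / R_exp^2; can exceed 1 by sampling noise."""
    if r_exp == 0:
        raise ZebuPopError("R_exp is zero; ratio undefined")
    return (r_obs / r_exp) ** 2


def breed_pair_matrix(
    panel: GenotypePanel, maf_filter: str = "all_snps", min_maf: float = 0.05
) -> pd.DataFrame:
    """All breed-pair (and breed-vs-pool) correlation results.

    ``maf_filter`` is ``"all_snps"`` or ``"maf_gt_005"`` (strict > ``min_maf``
    on the pooled frequencies).  Returns one row per unordered pair plus one
    row per breed against the pooled-all-animals frequency vector (the
    part–whole comparison).
    """
    if maf_filter not in ("all_snps", "maf_gt_005"):
        raise ValueError(f"unknown maf_filter {maf_filter!r}")
    breeds = panel.breeds()
    if len(breeds) < 2:
        raise ZebuPopError("need at least 2 breeds")
    by_breed = allele_frequencies(panel, "by_breed")
    pooled = allele_frequencies(panel, "pooled")
    keep = np.arange(panel.n_markers)
    if maf_filter == "maf_gt_005":
        keep = np.flatnonzero(np.nan_to_num(pooled.maf[0], nan=0.0) > min_maf)
        if len(keep) == 0:
            raise ZebuPopError("no markers pass the MAF filter")
    p_pool = pooled.freq[0][keep]
    vp = float(np.nanvar(p_pool))
    sizes = {b: len(panel.samples_in_breed(b)) for b in breeds}
    f = {b: by_breed.freq_for(b)[keep] for b in breeds}
    ve = {b: error_variance(f[b], sizes[b]) for b in breeds}
    used = maf_filter == "maf_gt_005"

    rows = []
    for i, a in enumerate(breeds):
        for b in breeds[i + 1 :]:
            r_obs = observed_corr(f[a], f[b])
            r_exp = expected_corr(vp, ve[a], ve[b])
            rows.append(
                FreqCorrResult(a, b, r_obs, r_exp, variance_explained_ratio(r_obs, r_exp),
                               sizes[a], sizes[b], vp, ve[a], ve[b], used)
            )
        # part-whole: breed against the pooled meta-population frequencies
        r_obs = observed_corr(f[a], p_pool)
        r_exp = expected_corr(vp, ve[a], 0.0)
        rows.append(
            FreqCorrResult(a, POOL_LABEL, r_obs, r_exp,
                           variance_explained_ratio(r_obs, r_exp),
                           sizes[a], panel.n_samples, vp, ve[a], 0.0, used)
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def corr_matrix_table(results: pd.DataFrame, field: str = "r_obs") -> pd.DataFrame:
    """Square symmetric breed x breed table of one result field."""
    breeds = sorted(
        set(results.breed_a) | set(results.breed_b) - {POOL_LABEL}
    )
    breeds = [b for b in breeds if b != POOL_LABEL]
    out = pd.DataFrame(np.nan, index=breeds, columns=breeds)
    for _, row in results.iterrows():
        if row.breed_b == POOL_LABEL:
            continue
        out.loc[row.breed_a, row.breed_b] = row[field]
        out.loc[row.breed_b, row.breed_a] = row[field]
    np.fill_diagonal(out.values, 1.0 if field.startswith("r") else np.nan)
    return out
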