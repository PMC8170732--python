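"""F statistics and allele-frequency admixture statistics.

* F_IS per breed as Nei's heterozygote-deficit form, per locus
  ``1 - Ho/He`` with He = 2p(1-p), averaged unweighted over polymorphic loci
  (the SD across loci is reported alongside, plus the standard error of the
  mean for completeness).
* Pairwise F_ST as the Weir & Cockerham (1984) theta-hat: the ratio of
  summed variance components ``sum(a) / sum(a+b+c)`` over loci (ratio of
  sums, the estimator's recommended multi-locus aggregation), with per-locus
  components exposed for inspection.
* f3(A; B, C) and f4(A, B; C, D) from allele-frequency vectors, with a
  weighted delete-one block jackknife over contiguous SNP blocks (default
  1000 SNPs) giving standard errors and Z scores.  An f3 Z below -3 is the
  conventional admixture call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import GenotypePanel, ZebuPopError, _MISSING

Z_ADMIXED = -3.0  # f3 significance rule: call admixture when Z < -3


@dataclass
class FStatResult:
    statistic: str
    scope: tuple
    value: float
    per_locus: np.ndarray
    sd_loci: float
    se: float


@dataclass
class AdmixtureStat:
    kind: str
    populations: tuple
    estimate: float
    se: float
    z: float
    block_size: int
    n_blocks: int
    admixture_call: bool | None = None


# ---------------------------------------------------------------------------
# F_IS (Nei)
# ---------------------------------------------------------------------------


def _breed_counts(panel: GenotypePanel, breed):
    idx = panel.samples_in_breed(breed)
    if len(idx) < 2:
        raise ZebuPopError(f"breed {breed!r} needs >= 2 samples")
    sub = panel.calls[idx, :]
    called = sub != _MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0)
    het = ((sub == 1) & called).sum(axis=0)
    return n_called, alt, het


def fis_nei(panel: GenotypePanel, breed) -> FStatResult:
    """Within-breed inbreeding coefficient F_IS = mean_j (1 - Ho_j / He_j)."""
    n_called, alt, het = _breed_counts(panel, breed)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, alt / np.maximum(2 * n_called, 1), np.nan)
        ho = np.where(n_called > 0, het / np.maximum(n_called, 1), np.nan)
    he = 2.0 * p * (1.0 - p)
    poly = np.flatnonzero(np.nan_to_num(he, nan=0.0) > 0)
    if len(poly) == 0:
        raise ZebuPopError(f"no polymorphic loci in breed {breed!r}")
    per_locus = 1.0 - ho[poly] / he[poly]
    value = float(per_locus.mean())
    sd = float(per_locus.std(ddof=1)) if len(poly) > 1 else np.nan
    return FStatResult("FIS", (breed,), value, per_locus, sd, sd / np.sqrt(len(poly)))


# ---------------------------------------------------------------------------
# Weir–Cockerham F_ST
# ---------------------------------------------------------------------------


def _wc_components(n1, p1, h1, n2, p2, h2):
    """Weir & Cockerham (1984) a, b, c variance components, two populations.

    Arrays are per locus: n_i called diploids, p_i alt frequency, h_i
    observed heterozygote fraction.
    """
    r = 2.0
    n_bar = (n1 + n2) / r
    nc = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / nc) * (
        s2 - (p_bar * (1 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0) / (n_bar - 1.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1 - p_bar) - s2 * (r - 1.0) / r - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
    )
    c = h_bar / 2.0
    return a, b, c


def fst_weir_cockerham(panel: GenotypePanel, breed_a, breed_b) -> FStatResult:
    """Multi-locus theta-hat = sum(a) / sum(a+b+c) over shared polymorphic loci."""
    na, alt_a, het_a = _breed_counts(panel, breed_a)
    nb, alt_b, het_b = _breed_counts(panel, breed_b)
    ok = (na > 0) & (nb > 0)
    p1 = alt_a / np.maximum(2 * na, 1)
    p2 = alt_b / np.maximum(2 * nb, 1)
    h1 = het_a / np.maximum(na, 1)
    h2 = het_b / np.maximum(nb, 1)
    # a locus contributes only if polymorphic somewhere across the pair
    poly = ok & ~((p1 == 0) & (p2 == 0)) & ~((p1 == 1) & (p2 == 1))
    if not poly.any():
        raise ZebuPopError("both breeds monomorphic at every shared locus")
    a, b, c = _wc_components(
        na[poly].astype(float), p1[poly], h1[poly],
        nb[poly].astype(float), p2[poly], h2[poly],
    )
    denom = a + b + c
    total = float(denom.sum())
    if total == 0:
        raise ZebuPopError("degenerate variance components")
    theta = float(a.sum()) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        per_locus = np.where(denom != 0, a / denom, np.nan)
    n_def = int(np.sum(~np.isnan(per_locus)))
    sd = float(np.nanstd(per_locus, ddof=1)) if n_def > 1 else float("nan")
    return FStatResult(
        "FST", (breed_a, breed_b), theta, per_locus, sd, sd / np.sqrt(poly.sum())
    )


def fst_matrix(panel: GenotypePanel, breeds: list | None = None) -> pd.DataFrame:
    """Symmetric breed x breed matrix of pairwise Weir–Cockerham theta-hat."""
    breeds = breeds if breeds is not None else panel.breeds()
    if len(breeds) < 2:
        raise ZebuPopError("need at least 2 breeds")
    out = pd.DataFrame(0.0, index=breeds, columns=breeds)
    for i, a in enumerate(breeds):
        for b in breeds[i + 1 :]:
            v = fst_weir_cockerham(panel, a, b).value
            out.loc[a, b] = v
            out.loc[b, a] = v
    return out


# ---------------------------------------------------------------------------
# f3 / f4 with weighted block jackknife
# ---------------------------------------------------------------------------


def _blocks(m: int, block_size: int):
    """Contiguous SNP blocks; a trailing short block keeps its SNP count as weight."""
    edges = list(range(0, m, block_size)) + [m]
    spans = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    if len(spans) < 2:
        raise ZebuPopError("fewer than 2 blocks; reduce block_size or add markers")
    return spans


def _block_jackknife(per_locus: np.ndarray, block_size: int):
    """Weighted delete-one-block jackknife of a mean over loci.

    Returns (estimate, se, n_blocks) using the Busing et al. (1999) weighted
    jackknife variance, robust to an unequal trailing block.
    """
    m = len(per_locus)
    spans = _blocks(m, block_size)
    g = len(spans)
    total = per_locus.sum()
    est = total / m
    theta_del = np.empty(g)
    weights = np.empty(g)
    for j, (lo, hi) in enumerate(spans):
        mj = hi - lo
        theta_del[j] = (total - per_locus[lo:hi].sum()) / (m - mj)
        weights[j] = mj
    h = m / weights
    theta_j = g * est - np.sum((1.0 - weights / m) * theta_del)
    var = np.mean((h * est - (h - 1.0) * theta_del - theta_j) ** 2 / (h - 1.0))
    return float(est), float(np.sqrt(var)), g


def _het_correction(p: np.ndarray, n_diploid: int | None) -> np.ndarray:
    """Unbiased estimate of Var(p-hat) = p(1-p)/(2n-1), Patterson's correction."""
    if n_diploid is None:
        return np.zeros_like(p)
    return p * (1.0 - p) / (2.0 * n_diploid - 1.0)


def f3(
    freq_a: np.ndarray,
    freq_b: np.ndarray,
    freq_c: np.ndarray,
    block_size: int = 1000,
    n_a: int | None = None,
    correction: bool = True,
    populations: tuple = ("A", "B", "C"),
) -> AdmixtureStat:
    """f3(A; B, C) = mean (p_A - p_B)(p_A - p_C), negative under admixture of A.

    With ``correction`` (default on) the finite-sample bias of p_A is removed
    by subtracting the unbiased variance estimate p_A(1-p_A)/(2 n_A - 1) per
    locus; pass ``correction=False`` (or omit ``n_a``) for the raw product.
    """
    pa, pb, pc = (np.asarray(v, dtype=np.float64) for v in (freq_a, freq_b, freq_c))
    if not (pa.shape == pb.shape == pc.shape):
        raise ZebuPopError("frequency vectors differ in length")
    per_locus = (pa - pb) * (pa - pc)
    if correction and n_a is not None:
        per_locus = per_locus - _het_correction(pa, n_a)
    est, se, g = _block_jackknife(per_locus, block_size)
    z = est / se if se > 0 else (0.0 if est == 0 else float(np.inf * np.sign(est)))
    return AdmixtureStat("f3", populations, est, se, float(z), block_size, g, bool(z < Z_ADMIXED))


def f4(
    freq_a: np.ndarray,
    freq_b: np.ndarray,
    freq_c: np.ndarray,
    freq_d: np.ndarray,
    block_size: int = 1000,
    populations: tuple = ("A", "B", "C", "D"),
) -> AdmixtureStat:
    """f4(A, B; C, D) = mean (p_A - p_B)(p_C - p_D); zero under treeness."""
    pa, pb, pc, pd_ = (np.asarray(v, dtype=np.float64) for v in (freq_a, freq_b, freq_c, freq_d))
    if not (pa.shape == pb.shape == pc.shape == pd_.shape):
        raise ZebuPopError("frequency vectors differ in length")
    per_locus = (pa - pb) * (pc - pd_)
    est, se, g = _block_jackknife(per_locus, block_size)
    z = est / se if se > 0 else 0.0
    return AdmixtureStat("f4", populations, est, se, float(z), block_size, g)
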