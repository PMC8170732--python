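"""Linkage disequilibrium decay and LD-based effective population size.

r² between marker pairs is the squared Pearson correlation of unphased
dosage vectors (the Rogers–Huff composite estimator, valid without phasing),
computed over samples with both calls present.  After the sample-size
adjustment

    r²_adj = r² - 1/(2n),

Sved's drift–recombination equilibrium E[r²] = 1/(1 + 4 N c) is inverted to

    Ne = (1 / 4c) (1 / r²_adj - 1),

where c is the map distance in Morgan at the 1 cM = 1 Mb assumption; the
estimate refers to the population t = 1/(2c) generations before present.

A trajectory combines a short-range scheme (pairs up to 2 Mb in 80 bins of
25 kb; representative c = bin midpoint) with a long-range scheme on a
marker-thinned panel where pairs are pooled harmonically so that t is the
integer 1..25 (t = round(1/(2d)) with representative c = 1/(2t)); an
equal-width alternative (25 bins over 2-50 Mb, c = midpoint) is selectable.
Bins with too few pairs or r²_adj outside (0, 1) are dropped with a log
entry; breeds with n <= 20 carry a small-sample caution flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import (
    GenotypePanel,
    ZebuPopError,
    EmptyResultError,
    allele_frequencies,
    filter_markers_by_maf,
    thin_markers,
)
from .relmat import grm_vanraden, prune_related

logger = logging.getLogger("zebupop")

MORGAN_PER_BP = 1e-8  # 1 cM = 1 Mb


@dataclass(frozen=True)
class NeConfig:
    """Knobs of the Ne-trajectory procedure (defaults mirror the pipeline)."""

    maf_min: float = 0.05
    grm_prune_threshold: float = 0.2
    thin_step: int = 7
    short_max_bp: int = 2_000_000
    short_bin_bp: int = 25_000
    long_max_bp: int = 50_000_000
    long_scheme: str = "harmonic"  # or "equal_width"
    min_pairs_per_bin: int = 100
    small_sample_n: int = 20


# ---------------------------------------------------------------------------
# Pairwise r²
# ---------------------------------------------------------------------------


def pairwise_r2(
    panel: GenotypePanel, max_dist_bp: int, min_dist_bp: int = 1, block: int = 1024
) -> pd.DataFrame:
    """All same-chromosome marker pairs within ``max_dist_bp``.

    Returns a DataFrame (dist_bp, r2, n) with n the complete-case sample
    count per pair; zero-variance pairs are skipped and counted in the log.
    """
    out_dist, out_r2, out_n = [], [], []
    skipped = 0
    pos_all = np.asarray(panel.markers.position_bp)
    for chrom in panel.markers.chromosomes():
        idx = panel.markers.chrom_indices(chrom)
        if len(idx) < 2:
            continue
        pos = pos_all[idx].astype(np.int64)
        calls = panel.calls[:, idx]
        miss = panel.missing_mask()[:, idx]
        v = np.where(miss, 0, calls).astype(np.float64)
        w = (~miss).astype(np.float64)
        v2 = v * v
        mc = len(idx)
        for lo in range(0, mc, block):
            hi = min(lo + block, mc)
            # partner window: markers ahead of lo within max_dist of position[hi-1]
            jmax = int(np.searchsorted(pos, pos[hi - 1] + max_dist_bp, side="right"))
            vb, wb, v2b = v[:, lo:hi], w[:, lo:hi], v2[:, lo:hi]
            vt, wt, v2t = v[:, lo:jmax], w[:, lo:jmax], v2[:, lo:jmax]
            n_cc = wb.T @ wt
            sx = vb.T @ wt
            sy = wb.T @ vt
            sxy = vb.T @ vt
            sxx = v2b.T @ wt
            syy = wb.T @ v2t
            with np.errstate(divide="ignore", invalid="ignore"):
                cov = n_cc * sxy - sx * sy
                varx = n_cc * sxx - sx * sx
                vary = n_cc * syy - sy * sy
                r2 = (cov * cov) / (varx * vary)
            d = pos[None, lo:jmax] - pos[:, None][lo:hi]
            take = (d >= min_dist_bp) & (d <= max_dist_bp)
            good = take & np.isfinite(r2) & (n_cc >= 2)
            skipped += int(take.sum() - good.sum())
            out_dist.append(d[good])
            out_r2.append(r2[good])
            out_n.append(n_cc[good])
    if skipped:
        logger.info("pairwise_r2: skipped %d zero-variance/degenerate pairs", skipped)
    if not out_dist:
        return pd.DataFrame(columns=["dist_bp", "r2", "n"])
    return pd.DataFrame(
        {
            "dist_bp": np.concatenate(out_dist),
            "r2": np.clip(np.concatenate(out_r2), 0.0, 1.0),
            "n": np.concatenate(out_n).astype(np.int64),
        }
    )


def adjust_r2(r2, n):
    """Sample-size adjustment r²_adj = r² - 1/(2n); may go non-positive."""
    return np.asarray(r2, dtype=np.float64) - 1.0 / (2.0 * np.asarray(n, dtype=np.float64))


def ld_decay_curve(
    pairs: pd.DataFrame, bin_width_bp: int = 10_000, max_dist_bp: int = 10_000_000
) -> pd.DataFrame:
    """Mean r² per half-open distance interval [k*w, (k+1)*w)."""
    if len(pairs) == 0:
        raise EmptyResultError("no pairs to bin")
    sub = pairs[pairs.dist_bp < max_dist_bp]
    k = (sub.dist_bp // bin_width_bp).astype(int)
    grouped = sub.groupby(k)
    out = pd.DataFrame(
        {
            "lo_bp": grouped.dist_bp.first().index * bin_width_bp,
            "hi_bp": (grouped.dist_bp.first().index + 1) * bin_width_bp,
            "mean_r2": grouped.r2.mean(),
            "mean_n": grouped.n.mean(),
            "n_pairs": grouped.size(),
        }
    ).reset_index(drop=True)
    out["c_morgan"] = (out.lo_bp + out.hi_bp) / 2.0 * MORGAN_PER_BP
    out["mean_r2_adj"] = adjust_r2(out.mean_r2, out.mean_n)
    return out


# ---------------------------------------------------------------------------
# Sved inversion
# ---------------------------------------------------------------------------


def sved_ne(r2_adj: float, c: float) -> float:
    """Ne = (1/4c)(1/r²_adj - 1); defined for r²_adj in (0, 1)."""
    if c <= 0:
        raise ValueError("c must be positive")
    if not 0 < r2_adj < 1:
        raise ZebuPopError(f"r2_adj={r2_adj} outside (0, 1); Ne undefined")
    return (1.0 / (4.0 * c)) * (1.0 / r2_adj - 1.0)


def sved_expected_r2(ne: float, c: float) -> float:
    """Model curve E[r²] = 1/(1 + 4 Ne c) (the inverse of :func:`sved_ne`)."""
    return 1.0 / (1.0 + 4.0 * ne * c)


def generation_for_distance(c: float) -> float:
    """Generations before present probed by map distance c: t = 1/(2c)."""
    if c <= 0:
        raise ValueError("c must be positive")
    return 1.0 / (2.0 * c)


# ---------------------------------------------------------------------------
# Trajectory orchestration
# ---------------------------------------------------------------------------


def _bin_rows(pairs: pd.DataFrame, assignments: np.ndarray, reps: dict):
    """Aggregate pairs into (t, c) bins; reps maps bin key -> representative c."""
    rows = []
    df = pairs.assign(key=assignments)
    for key, grp in df[df.key >= 0].groupby("key"):
        c = reps[int(key)]
        mean_r2 = float(grp.r2.mean())
        mean_n = float(grp.n.mean())
        rows.append(
            {
                "c_morgan": c,
                "t_generations": generation_for_distance(c),
                "mean_r2": mean_r2,
                "mean_n": mean_n,
                "r2_adj": float(adjust_r2(mean_r2, mean_n)),
                "n_pairs": int(len(grp)),
            }
        )
    return rows


def ne_trajectory(
    panel: GenotypePanel, breed, config: NeConfig = NeConfig()
) -> pd.DataFrame:
    """Full per-breed Ne trajectory following the published procedure.

    Steps: subset the breed; drop one member of every pair with VanRaden GRM
    off-diagonal > 0.2; keep markers with within-breed MAF > 0.05; short-range
    r² on that set (pairs to 2 Mb, 80 x 25-kb bins); long-range r² on the
    every-``thin_step``-th-marker subset (harmonic t = 1..25 pooling by
    default); invert each usable bin through Sved's formula.
    """
    idx = panel.samples_in_breed(breed)
    if len(idx) < 2:
        raise ZebuPopError(f"breed {breed!r} needs >= 2 samples")
    sub = panel.subset_samples(idx)
    grm = grm_vanraden(sub, scope=str(breed))
    retained, removed = prune_related(grm, config.grm_prune_threshold)
    if removed:
        logger.info("ne_trajectory[%s]: pruned %d related samples", breed, len(removed))
    sub = sub.subset_samples([sub.sample_ids.index(s) for s in retained])
    n = sub.n_samples
    sub = filter_markers_by_maf(sub, min_maf=config.maf_min)

    rows = []
    # short range: 80 bins of 25 kb, representative c = bin midpoint
    short = pairwise_r2(sub, max_dist_bp=config.short_max_bp)
    if len(short):
        k = short.dist_bp.to_numpy() // config.short_bin_bp  # half-open bins
        n_bins = config.short_max_bp // config.short_bin_bp
        k = np.where(k < n_bins, k, -1).astype(int)
        reps = {
            j: (j + 0.5) * config.short_bin_bp * MORGAN_PER_BP for j in range(n_bins)
        }
        rows += [dict(r, scheme="short") for r in _bin_rows(short, k, reps)]

    # long range on the thinned panel
    thin = thin_markers(sub, config.thin_step)
    lng = pairwise_r2(thin, max_dist_bp=config.long_max_bp,
                      min_dist_bp=config.short_max_bp)
    if len(lng):
        d_m = lng.dist_bp.to_numpy() * MORGAN_PER_BP
        if config.long_scheme == "harmonic":
            t = np.rint(1.0 / (2.0 * d_m)).astype(int)
            key = np.where((t >= 1) & (t <= 25), t, -1)
            reps = {j: 1.0 / (2.0 * j) for j in range(1, 26)}
        else:  # 25 equal-width bins over (2, 50] Mb
            width = (config.long_max_bp - config.short_max_bp) / 25.0
            j = ((lng.dist_bp.to_numpy() - config.short_max_bp) // width).astype(int)
            key = np.where((j >= 0) & (j < 25), j, -1)
            reps = {
                jj: (config.short_max_bp + (jj + 0.5) * width) * MORGAN_PER_BP
                for jj in range(25)
            }
        rows += [dict(r, scheme="long") for r in _bin_rows(lng, key, reps)]

    usable = []
    for r in rows:
        if r["n_pairs"] < config.min_pairs_per_bin:
            logger.info("ne_trajectory[%s]: bin t=%.3g dropped (%d pairs < floor %d)",
                        breed, r["t_generations"], r["n_pairs"], config.min_pairs_per_bin)
            continue
        if not 0 < r["r2_adj"] < 1:
            logger.info("ne_trajectory[%s]: bin t=%.3g dropped (r2_adj=%.4f not invertible)",
                        breed, r["t_generations"], r["r2_adj"])
            continue
        r["ne"] = sved_ne(r["r2_adj"], r["c_morgan"])
        usable.append(r)
    if not usable:
        raise EmptyResultError(f"no usable LD bins for breed {breed!r}")
    out = pd.DataFrame(usable).sort_values("t_generations").reset_index(drop=True)
    out.insert(0, "breed", breed)
    out["n_samples"] = n
    out["small_sample"] = n <= config.small_sample_n
    return out


def trajectory_summary(trajectory: pd.DataFrame, targets=(2000, 5, 1)) -> pd.DataFrame:
    """Nearest-t rows for headline generations (Table-2-style extract)."""
    rows = []
    for t in targets:
        i = (trajectory.t_generations - t).abs().idxmin()
        row = trajectory.loc[i].to_dict()
        row["target_generation"] = t
        rows.append(row)
    return pd.DataFrame(rows)
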