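"""Sliding-window detection of runs of homozygosity (ROH) and F_ROH.

The detector follows the Purcell/Neale sliding-window scheme as implemented
by detectRUNS-style tools:

1. slide a window of ``window_size_snps`` one SNP at a time along each
   chromosome; a window is *homozygous* when it contains at most
   ``max_het_per_window`` heterozygous and ``max_miss_per_window`` missing
   calls;
2. a SNP is *in-run* when the fraction of windows covering it that are
   homozygous is at least ``1 - window_threshold`` (SNPs near chromosome
   ends are covered by fewer windows; the fraction uses the windows that
   exist);
3. maximal stretches of in-run SNPs become candidate segments;
4. candidates are split wherever the gap between adjacent SNPs exceeds
   ``max_gap_bp``;
5. segments failing ``min_snps`` or ``min_length_bp`` are discarded.

F_ROH is the summed segment length divided by the SNP-covered autosomal
length (per chromosome, last minus first SNP position).  Segment coordinates
are reported 1-based inclusive, from first to last in-run SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genodata import GenotypePanel, MarkerMap, ZebuPopError, _MISSING


@dataclass(frozen=True)
class ROHParams:
    window_size_snps: int = 20
    window_threshold: float = 0.05
    min_snps: int = 20
    min_length_bp: int = 25_000
    max_gap_bp: int = 75_000
    max_het_per_window: int = 1
    max_miss_per_window: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.window_threshold <= 1:
            raise ValueError("window_threshold must be in (0, 1]")
        for name in ("window_size_snps", "min_snps", "min_length_bp", "max_gap_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ROHSegment:
    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def _in_run_snps(het_or_miss_bad: np.ndarray, hom_window: np.ndarray, w: int) -> np.ndarray:
    """Step 2: per-SNP fraction of covering homozygous windows.

    ``hom_window`` has one flag per window start (length L - w + 1); SNP i is
    covered by windows max(0, i-w+1) .. min(i, n_win-1).
    """
    n_win = len(hom_window)
    csum = np.concatenate([[0], np.cumsum(hom_window)])
    i = np.arange(len(het_or_miss_bad))
    lo = np.maximum(0, i - w + 1)
    hi = np.minimum(i, n_win - 1)
    covered = hi - lo + 1
    hom_cover = csum[hi + 1] - csum[lo]
    with np.errstate(invalid="ignore"):
        frac = np.where(covered > 0, hom_cover / np.maximum(covered, 1), 0.0)
    return frac


def detect_roh(panel: GenotypePanel, sample_id: str, params: ROHParams = ROHParams()) -> list:
    """Detect ROH segments for one sample.  Markers must be position-sorted."""
    try:
        si = panel.sample_ids.index(sample_id)
    except ValueError:
        raise ZebuPopError(f"unknown sample {sample_id!r}")
    w = params.window_size_snps
    segments = []
    pos_all = np.asarray(panel.markers.position_bp)
    for chrom in panel.markers.chromosomes():
        idx = panel.markers.chrom_indices(chrom)
        calls = panel.calls[si, idx]
        pos = pos_all[idx]
        L = len(idx)
        if L == 0:
            continue
        het = calls == 1
        miss = calls == _MISSING
        if L >= w:
            het_in_win = np.convolve(het.astype(np.int32), np.ones(w, dtype=np.int32), "valid")
            miss_in_win = np.convolve(miss.astype(np.int32), np.ones(w, dtype=np.int32), "valid")
            hom_window = (het_in_win <= params.max_het_per_window) & (
                miss_in_win <= params.max_miss_per_window
            )
            frac = _in_run_snps(het | miss, hom_window, w)
            in_run = frac >= 1.0 - params.window_threshold
        else:
            in_run = np.zeros(L, dtype=bool)
        # steps 3-5: maximal stretches, gap splitting, minima
        boundaries = np.flatnonzero(np.diff(np.concatenate([[0], in_run.view(np.int8), [0]])))
        for s, e in zip(boundaries[::2], boundaries[1::2]):
            run_pos = pos[s:e]
            gap_breaks = np.flatnonzero(np.diff(run_pos) > params.max_gap_bp)
            pieces = np.split(np.arange(s, e), gap_breaks + 1)
            for piece in pieces:
                if len(piece) < params.min_snps:
                    continue
                start, end = int(pos[piece[0]]), int(pos[piece[-1]])
                if end - start < params.min_length_bp:
                    continue
                segments.append(
                    ROHSegment(sample_id, str(chrom), start, end, int(len(piece)))
                )
    return segments


def froh(segments: list, markers: MarkerMap) -> float:
    """F_ROH = sum of segment lengths / SNP-covered genome length."""
    covered = 0
    pos = np.asarray(markers.position_bp)
    for chrom in markers.chromosomes():
        idx = markers.chrom_indices(chrom)
        if len(idx) > 1:
            covered += int(pos[idx[-1]] - pos[idx[0]])
    if covered == 0:
        raise ZebuPopError("marker map covers no length")
    total = sum(seg.length_bp for seg in segments)
    return total / covered


def detect_roh_panel(panel: GenotypePanel, params: ROHParams = ROHParams()) -> pd.DataFrame:
    """All samples' segments as a BED-like table (plus F_ROH per sample)."""
    rows = []
    for sid in panel.sample_ids:
        for seg in detect_roh(panel, sid, params):
            rows.append(
                {
                    "sample_id": seg.sample_id,
                    "chromosome": seg.chromosome,
                    "start_bp": seg.start_bp,
                    "end_bp": seg.end_bp,
                    "n_snps": seg.n_snps,
                    "length_bp": seg.length_bp,
                }
            )
    cols = ["sample_id", "chromosome", "start_bp", "end_bp", "n_snps", "length_bp"]
    return pd.DataFrame(rows, columns=cols)


def roh_breed_summary(
    panel: GenotypePanel,
    segments_table: pd.DataFrame,
    short_threshold_bp: int = 6_000_000,
    outlier_sd: float = 3.0,
) -> pd.DataFrame:
    """Per-breed F_ROH mean/SD, per-sample values, and share of segments < 6 Mb."""
    froh_by_sample = {}
    for sid in panel.sample_ids:
        sub = segments_table[segments_table.sample_id == sid]
        segs = [
            ROHSegment(sid, r.chromosome, int(r.start_bp), int(r.end_bp), int(r.n_snps))
            for r in sub.itertuples()
        ]
        froh_by_sample[sid] = froh(segs, panel.markers)
    labels = np.asarray(panel.breed_labels, dtype=object)
    rows = []
    for b in pd.unique(labels):
        sids = [panel.sample_ids[i] for i in np.flatnonzero(labels == b)]
        vals = np.array([froh_by_sample[s] for s in sids])
        segs = segments_table[segments_table.sample_id.isin(sids)]
        n_seg = len(segs)
        short = int((segs.length_bp < short_threshold_bp).sum()) if n_seg else 0
        mean, sd = float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        outliers = (
            [s for s, v in zip(sids, vals) if v > mean + outlier_sd * sd]
            if len(vals) > 1 and np.isfinite(sd)
            else []
        )
        rows.append(
            {
                "breed": b,
                "n": len(sids),
                "mean_froh": mean,
                "sd_froh": sd,
                "n_segments": n_seg,
                "share_segments_lt_6mb": short / n_seg if n_seg else np.nan,
                "outliers": ";".join(outliers),
            }
        )
    return pd.DataFrame(rows)
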