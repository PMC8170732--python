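"""Genotype panels: containers, QC filters, allele frequencies and file I/O.

The central object is the :class:`GenotypePanel` — an individuals x markers
matrix of alt-allele dosages (0/1/2, with a dedicated missing symbol) plus a
physical marker map and a breed label per sample.  Every downstream analysis
(GRM/PCA, F statistics, allele-frequency correlations, ROH scanning and
LD-based Ne estimation) consumes this type.

Conventions
-----------
* Dosages always count copies of ``MarkerMap.allele_alt``.  For PLINK 1 files
  the A1 allele (``.bim`` column 5) plays the role of the alt allele, so the
  two-bit code ``00`` (homozygous A1) maps to dosage 2.  For VCF the ALT
  allele is counted.
* Missing calls are exposed through :meth:`GenotypePanel.missing_mask` and as
  ``NaN`` in the float dosage matrix; the compact int8 storage uses an
  internal code that callers should not rely on.
* Positions are 1-based base pairs, as in ``.bim``/VCF.  Interval logic
  downstream uses half-open ``[start, end)`` windows internally.
* QC thresholds are strict: samples are kept when call rate > ``min_rate``
  and markers when MAF > ``min_maf``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("zebupop")

#: internal storage code for a missing call (never part of the public model)
_MISSING = -1

# complementary-base table used for strand reconciliation when merging panels
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ZebuPopError(Exception):
    """Base class for all package errors."""


class FormatError(ZebuPopError):
    """Malformed input file (bad magic bytes, unparsable records)."""


class ConsistencyError(ZebuPopError):
    """Inputs that parse but violate an invariant (duplicate ids, size mismatch)."""


class EmptyResultError(ZebuPopError):
    """A filter or computation removed everything."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerMap:
    """Physical map of biallelic SNP markers.

    Positions must be strictly increasing within each chromosome and marker
    ids unique; both are validated on construction.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    allele_ref: np.ndarray
    allele_alt: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.marker_id)
        for name in ("chromosome", "position_bp", "allele_ref", "allele_alt"):
            if len(getattr(self, name)) != n:
                raise ConsistencyError(f"marker map field {name!r} has wrong length")
        ids, counts = np.unique(np.asarray(self.marker_id), return_counts=True)
        if (counts > 1).any():
            dup = ids[counts > 1][:5]
            raise ConsistencyError(f"duplicate marker ids: {list(dup)}")
        if n and np.asarray(self.position_bp).min() < 0:
            raise ConsistencyError("negative base-pair position")
        pos = np.asarray(self.position_bp)
        chrom = np.asarray(self.chromosome)
        for c in pd.unique(chrom):
            p = pos[chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ConsistencyError(
                    f"positions not strictly increasing on chromosome {c}"
                )

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        return list(pd.unique(np.asarray(self.chromosome)))

    def chrom_indices(self, chrom) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.chromosome) == chrom)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        idx = np.asarray(idx)
        return MarkerMap(
            marker_id=np.asarray(self.marker_id)[idx],
            chromosome=np.asarray(self.chromosome)[idx],
            position_bp=np.asarray(self.position_bp)[idx],
            allele_ref=np.asarray(self.allele_ref)[idx],
            allele_alt=np.asarray(self.allele_alt)[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "position_bp": self.position_bp,
                "allele_ref": self.allele_ref,
                "allele_alt": self.allele_alt,
            }
        )


def marker_map_from_arrays(
    positions_by_chrom: dict, prefix: str = "snp"
) -> MarkerMap:
    """Build a MarkerMap from ``{chrom: positions}`` with generic A/G alleles."""
    chroms, pos = [], []
    for c, p in positions_by_chrom.items():
        p = np.sort(np.asarray(p, dtype=np.int64))
        chroms.append(np.full(len(p), str(c), dtype=object))
        pos.append(p)
    chrom = np.concatenate(chroms) if chroms else np.array([], dtype=object)
    pos = np.concatenate(pos) if pos else np.array([], dtype=np.int64)
    n = len(pos)
    return MarkerMap(
        marker_id=np.array([f"{prefix}{i}" for i in range(n)], dtype=object),
        chromosome=chrom,
        position_bp=pos,
        allele_ref=np.full(n, "A", dtype=object),
        allele_alt=np.full(n, "G", dtype=object),
    )


@dataclass
class GenotypePanel:
    """Diploid biallelic genotypes for a set of labeled samples.

    ``calls`` is an int8 (n_samples, n_markers) matrix of alt-allele dosages
    with the internal missing code; use :meth:`dosages` / :meth:`missing_mask`
    for analysis.
    """

    sample_ids: list
    breed_labels: list
    markers: MarkerMap
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), self.markers.n_markers):
            raise ConsistencyError(
                f"dosage matrix shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.markers.n_markers} markers"
            )
        if len(self.breed_labels) != len(self.sample_ids):
            raise ConsistencyError("breed label count != sample count")
        bad = ~np.isin(self.calls, (0, 1, 2, _MISSING))
        if bad.any():
            raise ConsistencyError("dosage entries outside {0,1,2,missing}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ConsistencyError("duplicate sample ids")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return self.markers.n_markers

    def missing_mask(self) -> np.ndarray:
        return self.calls == _MISSING

    def dosages(self) -> np.ndarray:
        """Float dosage matrix with missing calls as NaN."""
        d = self.calls.astype(np.float64)
        d[self.calls == _MISSING] = np.nan
        return d

    def breeds(self) -> list:
        return list(pd.unique(np.asarray(self.breed_labels, dtype=object)))

    def samples_in_breed(self, breed) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.breed_labels, dtype=object) == breed)

    # -- subsetting ---------------------------------------------------------

    def subset_samples(self, idx: Iterable[int]) -> "GenotypePanel":
        idx = np.asarray(list(idx), dtype=np.int64)
        return GenotypePanel(
            sample_ids=[self.sample_ids[i] for i in idx],
            breed_labels=[self.breed_labels[i] for i in idx],
            markers=self.markers,
            calls=self.calls[idx, :],
        )

    def subset_markers(self, idx: Iterable[int]) -> "GenotypePanel":
        idx = np.asarray(list(idx), dtype=np.int64)
        return GenotypePanel(
            sample_ids=list(self.sample_ids),
            breed_labels=list(self.breed_labels),
            markers=self.markers.subset(idx),
            calls=self.calls[:, idx],
        )


@dataclass
class AlleleFreqTable:
    """Alt-allele frequencies per group of samples.

    ``freq`` is (n_groups, n_markers); entries are NaN where a group has no
    non-missing call at a marker.  ``n_alleles`` counts non-missing *alleles*
    (2 x called diploids).
    """

    groups: list
    freq: np.ndarray
    n_alleles: np.ndarray
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=np.float64)
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.freq, initial=0.0) < -1e-12 or np.nanmax(
                self.freq, initial=0.0
            ) > 1 + 1e-12:
                raise ConsistencyError("allele frequency outside [0, 1]")

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.freq, 1.0 - self.freq)

    def freq_for(self, group) -> np.ndarray:
        return self.freq[self.groups.index(group)]


# ---------------------------------------------------------------------------
# Allele frequencies and QC filters
# ---------------------------------------------------------------------------


def allele_frequencies(panel: GenotypePanel, grouping: str = "pooled") -> AlleleFreqTable:
    """Alt-allele frequencies, ``grouping`` either ``"pooled"`` or ``"by_breed"``.

    p = (alt allele count) / (2 x non-missing diploid calls), computed only
    over non-missing calls; markers with no calls in a group get NaN.
    """
    if grouping not in ("pooled", "by_breed"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if panel.n_samples == 0:
        raise EmptyResultError("cannot compute frequencies for an empty panel")
    if grouping == "pooled":
        groups = ["ALL"]
        index_sets = [np.arange(panel.n_samples)]
    else:
        groups = panel.breeds()
        index_sets = [panel.samples_in_breed(b) for b in groups]
    freq = np.empty((len(groups), panel.n_markers))
    n_alleles = np.empty((len(groups), panel.n_markers), dtype=np.int64)
    for gi, idx in enumerate(index_sets):
        if len(idx) == 0:
            raise EmptyResultError(f"group {groups[gi]!r} has zero samples")
        sub = panel.calls[idx, :]
        called = sub != _MISSING
        alt = np.where(called, sub, 0).sum(axis=0)
        n2 = 2 * called.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n2 > 0, alt / np.maximum(n2, 1), np.nan)
        freq[gi] = p
        n_alleles[gi] = n2
    return AlleleFreqTable(groups=groups, freq=freq, n_alleles=n_alleles, markers=panel.markers)


def filter_samples_by_call_rate(
    panel: GenotypePanel, min_rate: float = 0.9
) -> GenotypePanel:
    """Keep samples whose fraction of non-missing calls is strictly > ``min_rate``."""
    if not 0 < min_rate <= 1:
        raise ValueError("min_rate must be in (0, 1]")
    called = (~panel.missing_mask()).mean(axis=1)
    keep = np.flatnonzero(called > min_rate)
    removed = [panel.sample_ids[i] for i in np.flatnonzero(called <= min_rate)]
    if removed:
        logger.info(
            "call-rate filter (> %.3g): removed %d of %d samples: %s",
            min_rate, len(removed), panel.n_samples, removed,
        )
    if len(keep) == 0:
        raise EmptyResultError("no samples pass the call-rate filter")
    return panel.subset_samples(keep)


def filter_markers_by_maf(
    panel: GenotypePanel,
    group: Sequence[int] | None = None,
    min_maf: float = 0.05,
) -> GenotypePanel:
    """Keep markers with MAF strictly > ``min_maf`` in ``group``.

    ``group`` is a sequence of sample indices (default: all samples).
    """
    idx = np.arange(panel.n_samples) if group is None else np.asarray(list(group))
    if len(idx) == 0:
        raise EmptyResultError("MAF filter group is empty")
    sub = panel.subset_samples(idx)
    freqs = allele_frequencies(sub, "pooled")
    maf = freqs.maf[0]
    keep = np.flatnonzero(np.nan_to_num(maf, nan=0.0) > min_maf)
    logger.info(
        "MAF filter (> %.3g): kept %d of %d markers", min_maf, len(keep), panel.n_markers
    )
    if len(keep) == 0:
        raise EmptyResultError("no markers pass the MAF filter")
    return panel.subset_markers(keep)


def thin_markers(panel: GenotypePanel, step: int = 7) -> GenotypePanel:
    """Retain every ``step``-th marker (indices 0, step, 2*step, ...) per chromosome."""
    if step < 1:
        raise ValueError("step must be >= 1")
    if step == 1:
        return panel
    keep = []
    for c in panel.markers.chromosomes():
        ci = panel.markers.chrom_indices(c)
        keep.append(ci[::step])
    keep = np.sort(np.concatenate(keep)) if keep else np.array([], dtype=np.int64)
    return panel.subset_markers(keep)


def subsample_breed(panel: GenotypePanel, max_n: int = 20, seed: int = 0) -> GenotypePanel:
    """Per breed, keep at most ``max_n`` samples chosen uniformly without replacement.

    Deterministic for a fixed seed; survivor order within the panel preserved.
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    rng = np.random.default_rng(seed)
    keep = []
    for b in panel.breeds():
        idx = panel.samples_in_breed(b)
        if len(idx) > max_n:
            idx = rng.choice(idx, size=max_n, replace=False)
        keep.append(np.sort(idx))
    keep = np.sort(np.concatenate(keep))
    return panel.subset_samples(keep)


# ---------------------------------------------------------------------------
# PLINK 1 binary I/O
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major PLINK 1 .bed
# two-bit code -> dosage of A1 (our alt): 00 hom A1, 01 missing, 10 het, 11 hom A2
_BED_DECODE = np.array([2, _MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, _MISSING: 0b01, 1: 0b10, 0: 0b11}


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write PLINK 1 ``.bed``/``.bim``/``.fam`` (SNP-major).

    The breed label is stored in the family-ID column of ``.fam``; the alt
    allele is written as A1 (``.bim`` column 5).
    """
    prefix = Path(prefix)
    m = panel.markers
    bim = pd.DataFrame(
        {
            0: m.chromosome,
            1: m.marker_id,
            2: np.zeros(m.n_markers),
            3: m.position_bp,
            4: m.allele_alt,
            5: m.allele_ref,
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            0: panel.breed_labels,
            1: panel.sample_ids,
            2: 0, 3: 0, 4: 0, 5: -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n = panel.n_samples
    n_bytes = (n + 3) // 4
    codes = np.empty_like(panel.calls, dtype=np.uint8)
    for dosage, code in _BED_ENCODE.items():
        codes[panel.calls == dosage] = code
    # pad samples to a multiple of 4 with hom-A2 (code 0b11 contributes zeros)
    padded = np.full((n_bytes * 4, panel.n_markers), 0b11, dtype=np.uint8)
    padded[:n] = codes
    shaped = padded.reshape(n_bytes, 4, panel.n_markers)
    byte_matrix = (
        shaped[:, 0, :]
        | (shaped[:, 1, :] << 2)
        | (shaped[:, 2, :] << 4)
        | (shaped[:, 3, :] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(byte_matrix.T.tobytes())  # SNP-major: all bytes of marker 0 first


def read_plink(prefix: str | Path) -> GenotypePanel:
    prefix = Path(prefix)
    bim_path, fam_path, bed_path = (
        prefix.with_suffix(".bim"), prefix.with_suffix(".fam"), prefix.with_suffix(".bed"),
    )
    for p in (bim_path, fam_path, bed_path):
        if not p.exists():
            raise FormatError(f"missing PLINK file: {p}")
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None, dtype={0: str})
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype={0: str, 1: str})
    markers = MarkerMap(
        marker_id=bim[1].to_numpy(dtype=object),
        chromosome=bim[0].to_numpy(dtype=object),
        position_bp=bim[3].to_numpy(dtype=np.int64),
        allele_alt=bim[4].to_numpy(dtype=object),
        allele_ref=bim[5].to_numpy(dtype=object),
    )
    raw = np.fromfile(bed_path, dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:3]) != _BED_MAGIC:
        raise FormatError(f"{bed_path} is not a SNP-major PLINK 1 .bed file")
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    body = raw[3:]
    if len(body) != n_bytes * m:
        raise ConsistencyError(
            f".bed payload is {len(body)} bytes, expected {n_bytes * m} "
            f"for {n} samples x {m} markers"
        )
    body = body.reshape(m, n_bytes)
    # expand each byte to 4 two-bit codes, low bits first
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    calls = _BED_DECODE[codes[:, :n]].T
    return GenotypePanel(
        sample_ids=list(fam[1].astype(str)),
        breed_labels=list(fam[0].astype(str)),
        markers=markers,
        calls=calls,
    )


# ---------------------------------------------------------------------------
# VCF I/O (diploid GT field; breed labels in a sidecar sample->breed TSV)
# ---------------------------------------------------------------------------


def write_vcf(panel: GenotypePanel, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write an uncompressed VCF (GT only) plus an optional sample->breed TSV."""
    path = Path(path)
    m = panel.markers
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", _MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in m.chromosomes():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in panel.sample_ids)
            + "\n"
        )
        for j in range(m.n_markers):
            row = [
                str(m.chromosome[j]), str(m.position_bp[j]), str(m.marker_id[j]),
                str(m.allele_ref[j]), str(m.allele_alt[j]), ".", "PASS", ".", "GT",
            ]
            row.extend(gt_strings[int(g)] for g in panel.calls[:, j])
            fh.write("\t".join(row) + "\n")
    if sidecar is not None:
        pd.DataFrame(
            {"sample_id": panel.sample_ids, "breed": panel.breed_labels}
        ).to_csv(sidecar, sep="\t", index=False)


def read_vcf(path: str | Path, sidecar: str | Path | None = None) -> GenotypePanel:
    """Read a diploid biallelic VCF; breed labels come from ``sidecar`` (TSV)."""
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - cyvcf2 is an optional extra
        return _read_vcf_text(path, sidecar)
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    ids, chroms, pos, ref, alt, rows = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise FormatError(
                f"multi-allelic record at {var.CHROM}:{var.POS}; split or filter first"
            )
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        gts = var.genotype.array()[:, :2]
        dos = gts.sum(axis=1).astype(np.int8)
        dos[(gts < 0).any(axis=1)] = _MISSING
        rows.append(dos)
    markers = MarkerMap(
        marker_id=np.asarray(ids, dtype=object),
        chromosome=np.asarray(chroms, dtype=object),
        position_bp=np.asarray(pos, dtype=np.int64),
        allele_ref=np.asarray(ref, dtype=object),
        allele_alt=np.asarray(alt, dtype=object),
    )
    calls = np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0), np.int8)
    breeds = _sidecar_breeds(samples, sidecar)
    return GenotypePanel(sample_ids=samples, breed_labels=breeds, markers=markers, calls=calls)


def _read_vcf_text(path: str | Path, sidecar: str | Path | None) -> GenotypePanel:
    """Minimal text fallback parser for uncompressed GT-only VCFs."""
    samples: list = []
    ids, chroms, pos, ref, alt, rows = [], [], [], [], [], []
    code = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "./.": _MISSING,
            "0|0": 0, "0|1": 1, "1|0": 1, "1|1": 2, ".|.": _MISSING}
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##fileformat=VCF"):
            raise FormatError(f"{path} lacks a VCF header")
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                continue
            f = line.rstrip("\n").split("\t")
            if "," in f[4]:
                raise FormatError(f"multi-allelic record at {f[0]}:{f[1]}")
            chroms.append(f[0]); pos.append(int(f[1]))
            ids.append(f[2] if f[2] != "." else f"{f[0]}:{f[1]}")
            ref.append(f[3]); alt.append(f[4])
            gt_index = f[8].split(":").index("GT")
            rows.append(
                np.array([code[g.split(":")[gt_index]] for g in f[9:]], dtype=np.int8)
            )
    markers = MarkerMap(
        marker_id=np.asarray(ids, dtype=object),
        chromosome=np.asarray(chroms, dtype=object),
        position_bp=np.asarray(pos, dtype=np.int64),
        allele_ref=np.asarray(ref, dtype=object),
        allele_alt=np.asarray(alt, dtype=object),
    )
    calls = np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0), np.int8)
    return GenotypePanel(
        sample_ids=samples,
        breed_labels=_sidecar_breeds(samples, sidecar),
        markers=markers,
        calls=calls,
    )


def _sidecar_breeds(samples: list, sidecar: str | Path | None) -> list:
    if sidecar is None:
        return ["UNKNOWN"] * len(samples)
    tab = pd.read_csv(sidecar, sep="\t", dtype=str)
    mapping = dict(zip(tab.iloc[:, 0], tab.iloc[:, 1]))
    missing = [s for s in samples if s not in mapping]
    if missing:
        raise ConsistencyError(f"sidecar lacks breed labels for samples: {missing[:5]}")
    return [mapping[s] for s in samples]


def read_genotypes(path: str | Path, format: str = "plink1", sidecar=None) -> GenotypePanel:
    """Read a genotype panel from PLINK 1 (``path`` = prefix) or VCF."""
    if format == "plink1":
        return read_plink(path)
    if format == "vcf":
        return read_vcf(path, sidecar)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Panel merging with allele reconciliation
# ---------------------------------------------------------------------------


def merge_panels(a: GenotypePanel, b: GenotypePanel) -> GenotypePanel:
    """Stack two panels sample-wise on their shared markers.

    Alleles are reconciled: if panel b has ref/alt swapped at a marker its
    dosage is flipped (g -> 2-g).  Strand-ambiguous A/T and C/G mismatches
    are refused.
    """
    ids_a = {mid: j for j, mid in enumerate(a.markers.marker_id)}
    shared = [(ids_a[mid], j) for j, mid in enumerate(b.markers.marker_id) if mid in ids_a]
    if not shared:
        raise ConsistencyError("panels share no markers")
    shared.sort()  # keep panel a's map order so positions stay increasing
    ja = np.array([s[0] for s in shared])
    jb = np.array([s[1] for s in shared])
    sub_a, sub_b = a.subset_markers(ja), b.subset_markers(jb)
    calls_b = sub_b.calls.copy()
    for k in range(sub_a.n_markers):
        ra, aa = sub_a.markers.allele_ref[k], sub_a.markers.allele_alt[k]
        rb, ab = sub_b.markers.allele_ref[k], sub_b.markers.allele_alt[k]
        if (ra, aa) == (rb, ab):
            continue
        if (ra, aa) == (ab, rb):
            if _COMPLEMENT.get(ra) == aa:  # A/T or C/G: swap is strand-ambiguous
                raise ConsistencyError(
                    f"ambiguous allele swap at {sub_a.markers.marker_id[k]} ({ra}/{aa})"
                )
            col = calls_b[:, k]
            flipped = np.where(col == _MISSING, _MISSING, 2 - col).astype(np.int8)
            calls_b[:, k] = flipped
        else:
            raise ConsistencyError(
                f"irreconcilable alleles at {sub_a.markers.marker_id[k]}: "
                f"{ra}/{aa} vs {rb}/{ab}"
            )
    return GenotypePanel(
        sample_ids=list(sub_a.sample_ids) + list(sub_b.sample_ids),
        breed_labels=list(sub_a.breed_labels) + list(sub_b.breed_labels),
        markers=sub_a.markers,
        calls=np.vstack([sub_a.calls, calls_b]),
    )
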