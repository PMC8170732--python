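"""Synthetic genotype panels with known truth.

Every analysis stage in this package is validated against data generated
here: breeds diverged from a common ancestral frequency pool under the
Balding–Nichols model (divergence parameterized by F, the expected Weir–
Cockerham F_ST), a deeply diverged second pool emulating the taurine/indicine
species split, recently admixed individuals, within-breed relatives, planted
runs of homozygosity, and chromosomes whose linkage disequilibrium encodes a
known effective-population-size history via a forward-in-time Wright–Fisher
simulation.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genodata import (
    GenotypePanel,
    MarkerMap,
    AlleleFreqTable,
    ConsistencyError,
    ZebuPopError,
    _MISSING,
    allele_frequencies,
    marker_map_from_arrays,
)

#: map distance per base pair at the 1 cM / Mb assumption
MORGAN_PER_BP = 1e-8


@dataclass(frozen=True)
class SimConfig:
    """Desk-scale scenario configuration for Balding–Nichols panels.

    ``breed_f`` is one Balding–Nichols F per breed (the expected divergence
    of that breed from the ancestral pool); ``taurine_pool_f`` parameterizes
    the deeply diverged second species pool used for admixture scenarios.
    """

    seed: int = 0
    n_per_breed: int = 50
    n_markers: int = 20_000
    breed_f: tuple = (0.02, 0.05, 0.1, 0.2)
    taurine_pool_f: float = 0.35
    ancestral_freq_range: tuple = (0.05, 0.95)
    n_chromosomes: int = 10
    chrom_length_bp: int = 50_000_000
    breed_names: tuple | None = None

    def __post_init__(self) -> None:
        for f in self.breed_f:
            if not 0 <= f < 1:
                raise ValueError("breed F must be in [0, 1)")
        if not 0 < self.taurine_pool_f < 1:
            raise ValueError("taurine_pool_f must be in (0, 1)")

    @property
    def n_breeds(self) -> int:
        return len(self.breed_f)

    def names(self) -> list:
        if self.breed_names is not None:
            return list(self.breed_names)
        return [f"BREED{k + 1}" for k in range(self.n_breeds)]


@dataclass(frozen=True)
class NeTrajectory:
    """Piecewise-constant effective size history.

    ``steps`` is a sequence of ``(t_back, Ne)`` with strictly increasing
    generations; Ne applies to all generations back to ``t_back`` (inclusive)
    since the previous step.  Generations older than the last step use its Ne.
    """

    steps: tuple

    def __post_init__(self) -> None:
        ts = [t for t, _ in self.steps]
        if not ts or any(t < 1 for t in ts):
            raise ValueError("generations must be >= 1")
        if not all(b > a for a, b in zip(ts, ts[1:])):
            raise ValueError("generations must be strictly increasing")
        if any(ne < 2 for _, ne in self.steps):
            raise ZebuPopError("Ne < 2 is not simulable")

    def ne_at(self, t_back: int) -> int:
        for t, ne in self.steps:
            if t_back <= t:
                return ne
        return self.steps[-1][1]

    @property
    def span(self) -> int:
        return self.steps[-1][0]

    @property
    def max_ne(self) -> int:
        return max(ne for _, ne in self.steps)


# ---------------------------------------------------------------------------
# Balding–Nichols breed panels
# ---------------------------------------------------------------------------


def _bn_breed_freqs(p_anc: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Draw one breed's frequencies: Beta(p(1-F)/F, (1-p)(1-F)/F) around p."""
    if f <= 0:
        return p_anc.copy()
    a = p_anc * (1 - f) / f
    b = (1 - p_anc) * (1 - f) / f
    return rng.beta(a, b)


def balding_nichols_panel(config: SimConfig, return_truth: bool = False):
    """Simulate diverged breeds from one ancestral frequency pool.

    Genotypes are Binomial(2, p_breed) per marker (HWE within breed, no LD).
    With ``return_truth`` the ancestral and per-breed frequency vectors are
    returned alongside the panel for test assertions.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=config.n_markers)
    names = config.names()
    breed_freqs = {}
    blocks, breed_labels, sample_ids = [], [], []
    for k, name in enumerate(names):
        p_k = _bn_breed_freqs(p_anc, config.breed_f[k], rng)
        breed_freqs[name] = p_k
        g = rng.binomial(2, p_k, size=(config.n_per_breed, config.n_markers))
        blocks.append(g.astype(np.int8))
        breed_labels.extend([name] * config.n_per_breed)
        sample_ids.extend(f"{name}_{i}" for i in range(config.n_per_breed))
    markers = _spread_markers(config)
    panel = GenotypePanel(
        sample_ids=sample_ids,
        breed_labels=breed_labels,
        markers=markers,
        calls=np.vstack(blocks),
    )
    if return_truth:
        return panel, {"ancestral_p": p_anc, "breed_freqs": breed_freqs}
    return panel


def _spread_markers(config: SimConfig) -> MarkerMap:
    """Place n_markers evenly over the configured chromosomes."""
    per = np.full(config.n_chromosomes, config.n_markers // config.n_chromosomes)
    per[: config.n_markers % config.n_chromosomes] += 1
    positions = {}
    for c in range(config.n_chromosomes):
        m = per[c]
        if m:
            spacing = max(config.chrom_length_bp // (m + 1), 1)
            positions[f"{c + 1}"] = (np.arange(m) + 1) * spacing
    return marker_map_from_arrays(positions)


def pool_freq_table(config: SimConfig, which: str, seed_offset: int = 0) -> AlleleFreqTable:
    """True frequency pools for admixture scenarios.

    ``which`` selects ``"indicine"`` or ``"taurine"``: both are Balding–
    Nichols draws around the same ancestral vector, the taurine one with the
    deep ``taurine_pool_f`` divergence.
    """
    rng = np.random.default_rng(config.seed + seed_offset)
    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=config.n_markers)
    f = {"indicine": min(config.breed_f), "taurine": config.taurine_pool_f}[which]
    p = _bn_breed_freqs(p_anc, f, rng)
    markers = _spread_markers(config)
    return AlleleFreqTable(
        groups=[which.upper()],
        freq=p[None, :],
        n_alleles=np.full((1, config.n_markers), 10**9, dtype=np.int64),
        markers=markers,
    )


# ---------------------------------------------------------------------------
# Forward Wright–Fisher with recombination (known-Ne LD)
# ---------------------------------------------------------------------------


def wright_fisher_simulate(
    trajectory: NeTrajectory,
    n_sample: int,
    chrom_length_bp: int,
    n_chromosomes: int,
    marker_density: float,
    seed: int,
    burn_in: int | None = None,
    init_freq_range: tuple = (0.1, 0.9),
    breed_label: str = "SIM",
) -> GenotypePanel:
    """Forward-in-time diploid Wright–Fisher with uniform recombination.

    Haplotypes are initialized as independent Bernoulli draws at segregating
    sites (no mutation afterwards), evolved for ``burn_in`` generations at the
    oldest Ne (default 4 x max Ne, enough to approach drift–recombination
    equilibrium at the distances analyzed downstream) and then through the
    trajectory from its oldest step to the present.  Recombination is uniform
    at 1 cM/Mb with free recombination between chromosomes; mating is random
    (selfing allowed, as in the canonical model).  The final generation is
    sampled without replacement.
    """
    rng = np.random.default_rng(seed)
    if burn_in is None:
        burn_in = 4 * trajectory.max_ne
    positions = {
        f"{c + 1}": np.unique(
            rng.integers(1, chrom_length_bp, size=max(1, rng.poisson(marker_density * chrom_length_bp)))
        )
        for c in range(n_chromosomes)
    }
    markers = marker_map_from_arrays(positions)
    chrom_slices = []
    start = 0
    for c in markers.chromosomes():
        idx = markers.chrom_indices(c)
        pos_m = np.asarray(markers.position_bp)[idx].astype(np.float64) * MORGAN_PER_BP
        chrom_slices.append((slice(start, start + len(idx)), pos_m, chrom_length_bp * MORGAN_PER_BP))
        start += len(idx)
    m_total = markers.n_markers

    ne_anc = trajectory.ne_at(trajectory.span)
    p0 = rng.uniform(*init_freq_range, size=m_total)
    hap = (rng.random((2 * ne_anc, m_total)) < p0).astype(np.int8)

    # generation schedule: burn-in at ancestral Ne, then trajectory to present
    sizes = [ne_anc] * burn_in + [trajectory.ne_at(t) for t in range(trajectory.span, 0, -1)]
    for ne_next in sizes:
        hap = _next_generation(hap, ne_next, chrom_slices, rng)

    n_final = hap.shape[0] // 2
    if n_sample > n_final:
        raise ZebuPopError(f"cannot sample {n_sample} diploids from Ne={n_final}")
    pick = rng.choice(n_final, size=n_sample, replace=False)
    calls = (hap[2 * pick] + hap[2 * pick + 1]).astype(np.int8)
    return GenotypePanel(
        sample_ids=[f"{breed_label}_{i}" for i in range(n_sample)],
        breed_labels=[breed_label] * n_sample,
        markers=markers,
        calls=calls,
    )


def _next_generation(hap, ne_next, chrom_slices, rng):
    """One Wright–Fisher generation: 2*ne_next gametes from random parents."""
    n_parent = hap.shape[0] // 2
    parents = rng.integers(0, n_parent, size=2 * ne_next)
    out = np.empty((2 * ne_next, hap.shape[1]), dtype=np.int8)
    for sl, pos_m, len_m in chrom_slices:
        h_start = rng.integers(0, 2, size=2 * ne_next)
        n_co = rng.poisson(len_m, size=2 * ne_next)
        # bulk path: no crossover on this chromosome -> copy one parental haplotype
        out[:, sl] = hap[2 * parents + h_start][:, sl]
        for g in np.flatnonzero(n_co):
            cuts = np.sort(rng.uniform(0.0, len_m, size=n_co[g]))
            parity = (np.searchsorted(cuts, pos_m) + h_start[g]) % 2
            ha = hap[2 * parents[g], sl]
            hb = hap[2 * parents[g] + 1, sl]
            out[g, sl] = np.where(parity == 0, ha, hb)
    return out


# ---------------------------------------------------------------------------
# Admixed individuals
# ---------------------------------------------------------------------------


def admix_individuals(
    freqs_a: AlleleFreqTable,
    freqs_b: AlleleFreqTable,
    q: np.ndarray,
    seed: int,
    breed_label: str = "ADMIXED",
) -> GenotypePanel:
    """Draw individuals whose alleles come from pool a with probability q.

    ``q`` is one ancestry fraction per individual; each of the two alleles at
    each marker independently picks pool a (probability ``q_i``) or pool b
    and is then Bernoulli at that pool's frequency.
    """
    pa, pb = freqs_a.freq[0], freqs_b.freq[0]
    if pa.shape != pb.shape or freqs_a.markers.n_markers != freqs_b.markers.n_markers:
        raise ConsistencyError("frequency pools are on different marker sets")
    if not np.array_equal(freqs_a.markers.marker_id, freqs_b.markers.marker_id):
        raise ConsistencyError("frequency pools are on different marker sets")
    q = np.asarray(q, dtype=np.float64)
    rng = np.random.default_rng(seed)
    n, m = len(q), len(pa)
    calls = np.zeros((n, m), dtype=np.int8)
    for allele in range(2):
        from_a = rng.random((n, m)) < q[:, None]
        p = np.where(from_a, pa[None, :], pb[None, :])
        calls += (rng.random((n, m)) < p).astype(np.int8)
    return GenotypePanel(
        sample_ids=[f"{breed_label}_{i}" for i in range(n)],
        breed_labels=[breed_label] * n,
        markers=freqs_a.markers,
        calls=calls,
    )


# ---------------------------------------------------------------------------
# Planted ROH and injected relatives
# ---------------------------------------------------------------------------


def plant_roh(panel: GenotypePanel, segments: list, seed: int = 0) -> GenotypePanel:
    """Force homozygosity inside ``segments`` = [(sample_id, chrom, start_bp, end_bp)].

    Within each half-open [start, end) segment the sample's calls become
    homozygous for an allele drawn per marker at the pooled frequency —
    emulating an autozygous haplotype while respecting local frequencies.
    Overlapping segments for one sample are refused.
    """
    by_sample: dict = {}
    for sid, chrom, start, end in segments:
        if end <= start:
            raise ValueError("segment end must exceed start")
        key = (sid, chrom)
        for s, e in by_sample.get(key, []):
            if start < e and s < end:
                raise ConsistencyError(f"overlapping planted segments for {sid} on {chrom}")
        by_sample.setdefault(key, []).append((start, end))
    if not segments:
        return panel
    rng = np.random.default_rng(seed)
    p = allele_frequencies(panel, "pooled").freq[0]
    calls = panel.calls.copy()
    sample_index = {s: i for i, s in enumerate(panel.sample_ids)}
    chrom_arr = np.asarray(panel.markers.chromosome)
    pos = np.asarray(panel.markers.position_bp)
    for sid, chrom, start, end in segments:
        i = sample_index[sid]
        in_seg = (chrom_arr == chrom) & (pos >= start) & (pos < end)
        j = np.flatnonzero(in_seg)
        if len(j) == 0:
            continue
        alt_allele = rng.random(len(j)) < p[j]
        calls[i, j] = np.where(alt_allele, 2, 0).astype(np.int8)
    return GenotypePanel(
        sample_ids=list(panel.sample_ids),
        breed_labels=list(panel.breed_labels),
        markers=panel.markers,
        calls=calls,
    )


def inject_relatives(panel: GenotypePanel, pairs: int, kinship: str, seed: int):
    """Append offspring created by Mendelian transmission with recombination.

    ``kinship`` is ``"parent_offspring"`` (one child per sampled parent pair;
    the truth pair is parent/child) or ``"full_sib"`` (two children per pair;
    the truth pair is the two sibs).  Parental genotypes are phased naively
    (heterozygotes randomly), which leaves within-parent haplotypes only
    approximately realistic but preserves the pedigree expectations the GRM
    tests rely on.  Returns ``(panel_with_offspring, truth_pairs)``.
    """
    if pairs == 0:
        return panel, []
    if kinship not in ("parent_offspring", "full_sib"):
        raise ValueError(f"unknown kinship {kinship!r}")
    if panel.n_samples < 2 * pairs:
        raise ZebuPopError("not enough samples to draw parents")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(panel.n_samples, size=2 * pairs, replace=False)
    chrom_slices = _panel_chrom_slices(panel)
    new_calls, new_ids, new_breeds, truth = [], [], [], []
    for k in range(pairs):
        ia, ib = int(chosen[2 * k]), int(chosen[2 * k + 1])
        hap_a = _phase_naive(panel.calls[ia], rng)
        hap_b = _phase_naive(panel.calls[ib], rng)
        n_children = 2 if kinship == "full_sib" else 1
        child_ids = []
        for c in range(n_children):
            child = _meiosis(hap_a, chrom_slices, rng) + _meiosis(hap_b, chrom_slices, rng)
            cid = f"OFFSPRING_{k}_{c}"
            new_calls.append(child.astype(np.int8))
            new_ids.append(cid)
            new_breeds.append(panel.breed_labels[ia])
            child_ids.append(cid)
        if kinship == "parent_offspring":
            truth.append((panel.sample_ids[ia], child_ids[0], 0.5))
        else:
            truth.append((child_ids[0], child_ids[1], 0.5))
    out = GenotypePanel(
        sample_ids=list(panel.sample_ids) + new_ids,
        breed_labels=list(panel.breed_labels) + new_breeds,
        markers=panel.markers,
        calls=np.vstack([panel.calls, np.vstack(new_calls)]),
    )
    return out, truth


def _panel_chrom_slices(panel: GenotypePanel):
    out = []
    pos = np.asarray(panel.markers.position_bp)
    for c in panel.markers.chromosomes():
        idx = panel.markers.chrom_indices(c)
        pos_m = pos[idx].astype(np.float64) * MORGAN_PER_BP
        length = pos_m[-1] - pos_m[0] if len(idx) > 1 else 0.0
        out.append((idx, pos_m, max(length, 1e-9)))
    return out


def _phase_naive(calls: np.ndarray, rng) -> np.ndarray:
    """(2, M) pseudo-haplotypes: homs split 0/0 or 1/1, hets randomized."""
    m = len(calls)
    hap = np.zeros((2, m), dtype=np.int8)
    hom_alt = calls == 2
    hap[:, hom_alt] = 1
    het = calls == 1
    which = rng.integers(0, 2, size=het.sum())
    hap[0, np.flatnonzero(het)] = which
    hap[1, np.flatnonzero(het)] = 1 - which
    miss = calls == _MISSING
    if miss.any():  # transmit a frequency-agnostic random allele
        hap[:, miss] = rng.integers(0, 2, size=(2, miss.sum()))
    return hap


def _meiosis(hap: np.ndarray, chrom_slices, rng) -> np.ndarray:
    gamete = np.empty(hap.shape[1], dtype=np.int8)
    for idx, pos_m, length in chrom_slices:
        start = rng.integers(0, 2)
        n_co = rng.poisson(length)
        if n_co == 0:
            gamete[idx] = hap[start, idx]
        else:
            cuts = np.sort(rng.uniform(pos_m[0], pos_m[0] + length, size=n_co))
            parity = (np.searchsorted(cuts, pos_m) + start) % 2
            gamete[idx] = np.where(parity == 0, hap[0, idx], hap[1, idx])
    return gamete
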