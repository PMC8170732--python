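"""End-to-end pipeline: QC -> admixture gate -> GRM/PCA -> diversity -> ROH -> Ne.

The driver reproduces the published analysis order on any labeled panel:
sample call-rate QC and per-breed subsampling first, then the supervised
taurine-ancestry gate whose exclusion list feeds every later stage, then
per-scope GRM/PCA, the diversity battery (F_IS table with GRM element
summaries, allele-frequency correlation matrices, the F_ST matrix, f3/f4
tables), ROH detection and finally per-breed Ne trajectories.  Every stage
writes a TSV artifact into the output directory and appends structured
counts to ``pipeline_log.tsv``; the fully serialized configuration is
written alongside so each number is recomputable from config + seed.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genodata, relmat, freqcorr, fstats, rohscan, ancestry, ldne
from .genodata import GenotypePanel, ZebuPopError
from .rohscan import ROHParams

logger = logging.getLogger("zebupop")


@dataclass
class PipelineConfig:
    """Every threshold of the analysis in one serializable block."""

    input_prefix: str = ""
    input_format: str = "plink1"
    sidecar: str | None = None
    output_dir: str = "zebupop_out"
    seed: int = 0
    taurine_labels: tuple = ()
    reference_labels: tuple = ()  # breeds used as supervised references
    min_call_rate: float = 0.9
    taurine_gate: float = 0.01
    maf_min: float = 0.05
    grm_prune_threshold: float = 0.2
    max_per_breed: int = 20
    min_breed_n_for_ne: int = 2
    thin_step: int = 7
    block_size_snps: int = 1000
    roh: ROHParams = field(default_factory=ROHParams)
    ne: ldne.NeConfig = field(default_factory=ldne.NeConfig)
    run_ne: bool = True
    run_roh: bool = True
    pca_components: int = 4

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _log_stage(records: list, stage: str, **counts) -> None:
    records.append({"stage": stage, **counts})
    logger.info("stage %s: %s", stage, counts)


def run_pipeline(config: PipelineConfig, panel: GenotypePanel | None = None) -> dict:
    """Run every stage; returns the artifact tables keyed by name."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log: list = []
    artifacts: dict = {}

    if panel is None:
        panel = genodata.read_genotypes(
            config.input_prefix, config.input_format, sidecar=config.sidecar
        )
    _log_stage(log, "input", n_samples=panel.n_samples, n_markers=panel.n_markers)

    # --- QC ---------------------------------------------------------------
    panel = genodata.filter_samples_by_call_rate(panel, config.min_call_rate)
    panel = genodata.subsample_breed(panel, config.max_per_breed, seed=config.seed)
    _log_stage(log, "qc", n_samples=panel.n_samples, n_markers=panel.n_markers)

    # --- supervised ancestry gate ------------------------------------------
    ref_labels = set(config.reference_labels) or set(panel.breeds())
    ref_idx = [
        i for i, b in enumerate(panel.breed_labels) if b in ref_labels
    ]
    refs = ancestry.ReferencePanelFreqs.from_panel(
        panel.subset_samples(ref_idx), set(config.taurine_labels)
    )
    props = ancestry.panel_proportions(panel, refs)
    props = ancestry.classify_admixed(props, config.taurine_gate)
    props.to_csv(out / "ancestry_proportions.tsv", sep="\t", index=False)
    artifacts["ancestry"] = props
    excluded = set(props.loc[props.status == "admixed", "sample_id"])
    _log_stage(log, "gate", n_admixed=len(excluded), n_pure=panel.n_samples - len(excluded))

    # PCA before gating (full panel) and after (pure panel)
    grm_all = relmat.grm_vanraden(panel, scope="all_pre_gate")
    _write_pca(relmat.pca_from_grm(grm_all, min(config.pca_components, panel.n_samples)),
               panel, out / "pca_pre_gate.tsv")

    keep = [i for i, s in enumerate(panel.sample_ids) if s not in excluded]
    if not keep:
        raise ZebuPopError("gate excluded every sample")
    pure = panel.subset_samples(keep)
    _log_stage(log, "post_gate", n_samples=pure.n_samples, n_markers=pure.n_markers)

    # --- per-scope GRM + PCA ------------------------------------------------
    scopes = {"study": [b for b in pure.breeds() if b not in set(config.taurine_labels)]}
    if config.taurine_labels:
        scopes["taurine"] = [b for b in pure.breeds() if b in set(config.taurine_labels)]
    grms = {}
    for scope, breeds in scopes.items():
        idx = [i for i, b in enumerate(pure.breed_labels) if b in set(breeds)]
        if len(idx) < 2:
            continue
        sub = pure.subset_samples(idx)
        g = relmat.grm_vanraden(sub, scope=scope)
        grms[scope] = (g, sub)
        relmat.export_grm_tsv(g, out / f"grm_{scope}.tsv")
        _write_pca(relmat.pca_from_grm(g, min(config.pca_components, sub.n_samples)),
                   sub, out / f"pca_{scope}.tsv")

    # --- diversity battery --------------------------------------------------
    study_g, study_panel = grms["study"]
    summary = relmat.grm_breed_summary(study_g, study_panel.breed_labels)
    fis_rows = []
    for b in study_panel.breeds():
        r = fstats.fis_nei(study_panel, b)
        fis_rows.append({"breed": b, "fis": r.value, "sd_loci": r.sd_loci, "se": r.se})
    table1 = summary.merge(pd.DataFrame(fis_rows), on="breed")
    table1.to_csv(out / "diversity_table.tsv", sep="\t", index=False)
    artifacts["diversity"] = table1

    for flt in ("all_snps", "maf_gt_005"):
        fc = freqcorr.breed_pair_matrix(study_panel, flt, config.maf_min)
        fc.to_csv(out / f"freqcorr_{flt}.tsv", sep="\t", index=False)
        artifacts[f"freqcorr_{flt}"] = fc

    fstm = fstats.fst_matrix(study_panel)
    fstm.to_csv(out / "fst_matrix.tsv", sep="\t")
    artifacts["fst_matrix"] = fstm

    freqs = genodata.allele_frequencies(study_panel, "by_breed")
    sizes = {b: len(study_panel.samples_in_breed(b)) for b in freqs.groups}
    f3_rows, f4_rows = [], []
    breeds = freqs.groups
    for a in breeds:
        for b, c in itertools.combinations([x for x in breeds if x != a], 2):
            st = fstats.f3(freqs.freq_for(a), freqs.freq_for(b), freqs.freq_for(c),
                           config.block_size_snps, n_a=sizes[a], populations=(a, b, c))
            f3_rows.append({"A": a, "B": b, "C": c, "f3": st.estimate, "se": st.se,
                            "z": st.z, "admixed": st.admixture_call})
    if len(breeds) >= 4:
        for a, b, c, d in itertools.combinations(breeds, 4):
            st = fstats.f4(freqs.freq_for(a), freqs.freq_for(b),
                           freqs.freq_for(c), freqs.freq_for(d),
                           config.block_size_snps, populations=(a, b, c, d))
            f4_rows.append({"A": a, "B": b, "C": c, "D": d,
                            "f4": st.estimate, "se": st.se, "z": st.z})
    pd.DataFrame(f3_rows).to_csv(out / "f3_table.tsv", sep="\t", index=False)
    pd.DataFrame(f4_rows).to_csv(out / "f4_table.tsv", sep="\t", index=False)
    artifacts["f3"] = pd.DataFrame(f3_rows)
    artifacts["f4"] = pd.DataFrame(f4_rows)

    # --- ROH ---------------------------------------------------------------
    if config.run_roh:
        segs = rohscan.detect_roh_panel(study_panel, config.roh)
        segs.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
        roh_sum = rohscan.roh_breed_summary(study_panel, segs)
        roh_sum.to_csv(out / "roh_summary.tsv", sep="\t", index=False)
        artifacts["roh_segments"] = segs
        artifacts["roh_summary"] = roh_sum
        _log_stage(log, "roh", n_segments=len(segs))

    # --- Ne trajectories ----------------------------------------------------
    if config.run_ne:
        ne_tables = []
        for b in study_panel.breeds():
            if len(study_panel.samples_in_breed(b)) < config.min_breed_n_for_ne:
                continue
            try:
                ne_tables.append(ldne.ne_trajectory(study_panel, b, config.ne))
            except ZebuPopError as exc:
                logger.warning("Ne trajectory skipped for %s: %s", b, exc)
        if ne_tables:
            traj = pd.concat(ne_tables, ignore_index=True)
            traj.to_csv(out / "ne_trajectories.tsv", sep="\t", index=False)
            extract = pd.concat(
                [ldne.trajectory_summary(t) for t in ne_tables], ignore_index=True
            )
            extract.to_csv(out / "ne_summary.tsv", sep="\t", index=False)
            artifacts["ne"] = traj
            artifacts["ne_summary"] = extract
            _log_stage(log, "ne", n_breeds=len(ne_tables))

    pd.DataFrame(log).to_csv(out / "pipeline_log.tsv", sep="\t", index=False)
    artifacts["log"] = pd.DataFrame(log)
    return artifacts


def _write_pca(res, panel: GenotypePanel, path) -> None:
    df = pd.DataFrame(
        res.scores, columns=[f"PC{i + 1}" for i in range(res.scores.shape[1])]
    )
    df.insert(0, "sample_id", res.sample_ids)
    df.insert(1, "breed", panel.breed_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
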