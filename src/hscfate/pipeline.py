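"""End-to-end orchestration of the synthetic demonstration analysis.

``run_all`` simulates every input at the configured study conditions, runs
repopulation scoring/classification, clonal statistics, the chromatin-
accessibility core (DARs, clusters, open fractions, Lin DARs, motif
enrichment), and the single-cell QC/DE/score stack, then writes a
directory of TSV report tables. Every output embeds a run manifest
(package version, seed, config hash) in its header; re-running with the
same configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, accessibility as atac, clonogenic, io, repopulation as repop
from . import sc_expression as scx, simulate as sim

logger = logging.getLogger("hscfate")


@dataclass
class Thresholds:
    """The printed gating and significance rules, in one auditable place."""

    reconstitution_min_percent: float = 0.1
    lineage_min_percent: float = 0.01
    min_donor_events: int = 10
    fpkm_presence_min: float = 5.0
    presence_fraction: float = 1 / 3
    p_adj_aging: float = 1e-4
    p_adj_subset: float = 0.05
    p_adj_deg: float = 0.01
    min_abs_log2fc_deg: float = 1.0
    frip_min: float = 0.10
    motif_neg_ln_p_primary: float = 50.0
    motif_neg_ln_p_secondary: float = 10.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be positive")


@dataclass
class RunConfig:
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    reference_rule: str = "central80"
    reference_cohort_size: int = 50
    n_mice_per_group: int = 20
    atac_n_regions: int = 2000
    atac_samples_per_group: int = 5
    sc_cells_per_group: int = 150
    sc_n_genes: int = 1500

    def to_yaml(self, path=None) -> str:
        data = dataclasses.asdict(self)
        text = yaml.safe_dump(data, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        text = str(source)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        data = yaml.safe_load(text)
        thr = data.pop("thresholds", {})
        return cls(thresholds=Thresholds(**thr), **data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _manifest(config: RunConfig, stage: str) -> list[str]:
    return [
        f"hscfate {__version__}",
        f"stage: {stage}",
        f"seed: {config.seed}",
        f"config_hash: {config.config_hash()}",
    ]


def _write(df: pd.DataFrame, outdir: Path, name: str, config: RunConfig,
           index: bool = False) -> None:
    io.write_table(df, outdir / name, header_lines=_manifest(config, name),
                   index=index)
    logger.info("wrote %s (%d rows)", name, len(df))


def run_all(config: RunConfig, outdir) -> dict:
    """Run every stage on synthetic data; returns the in-memory report bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    report: dict = {}

    # --- transplantation & lineage bias -----------------------------------
    logger.info("stage repopulation: seed=%d", config.seed)
    tconfig = sim.TransplantSimConfig(
        n_mice_per_group=config.n_mice_per_group, seed=config.seed
    )
    pb, truth = sim.simulate_transplants(tconfig)
    ref = sim.simulate_reference_cohort(
        "adult", config.reference_cohort_size, seed=config.seed + 1
    )
    interval = repop.derive_reference_interval(
        ref["lm_ratio"], rule=config.reference_rule, reference_mode="adult"
    )
    calls = repop.classify_cohort(
        pb, interval,
        reconstitution_min_percent=thr.reconstitution_min_percent,
        min_events=thr.min_donor_events,
    )
    calls = calls.merge(truth[["mouse_id", "group", "n_clones",
                               "dominant_archetype"]], on="mouse_id")
    report["bias_calls"] = calls
    _write(calls, outdir, "lineage_bias_calls.tsv", config)
    engrafted = calls[(calls["n_clones"] == 1) & (calls["category"] != "not-reconstituted")]
    recovery = float((engrafted["category"] == engrafted["dominant_archetype"]).mean()) \
        if len(engrafted) else np.nan
    audit = {"single_clone_archetype_recovery": recovery,
             "n_single_clone_engrafted": int(len(engrafted))}

    summary = repop.durability_summary(
        pd.DataFrame({
            "group": calls["group"],
            "reconstituted": calls["category"] != "not-reconstituted",
        }),
    )
    _write(summary, outdir, "durability_summary.tsv", config)
    report["durability"] = summary

    # --- clonogenic --------------------------------------------------------
    rng = np.random.default_rng(config.seed + 2)
    wells = []
    for plate, mode, p_true in [("plate_sorted", "sorted_single", 0.5),
                                ("plate_manual", "manual_poisson", 0.5)]:
        lam = 1.0
        for w in range(72):
            if mode == "sorted_single":
                positive = rng.uniform() < p_true
            else:
                n_cells = rng.poisson(lam)
                positive = rng.uniform() < 1 - (1 - p_true) ** n_cells
            wells.append({"plate_id": plate, "well_id": f"w{w:02d}",
                          "seeding_mode": mode, "day": 11,
                          "readout": "megakaryocyte_present" if positive else "none"})
    well_df = pd.DataFrame(wells)
    clon = clonogenic.well_table_frequencies(well_df, lam=1.0)
    report["clonogenic"] = clon
    _write(clon, outdir, "clonogenic_frequencies.tsv", config)

    # --- chromatin accessibility -------------------------------------------
    logger.info("stage accessibility: %d regions", config.atac_n_regions)
    n_planted = max(20, config.atac_n_regions // 20)
    aconfig = sim.AtacSimConfig(
        n_regions=config.atac_n_regions,
        groups=(("CD49b-", "J"), ("CD49b-", "O"),
                ("CD49b+", "J"), ("CD49b+", "O")),
        n_samples_per_group=config.atac_samples_per_group,
        planted_sets=(
            sim.PlantedSet("aging_gain", n_planted,
                           {"CD49b-:O": 2.0, "CD49b+:O": 2.0},
                           motif_id="MOTIF_GATA", motif_prob=0.6),
            sim.PlantedSet("lineage", n_planted,
                           {"CD49b+:J": 2.0, "CD49b+:O": 2.0},
                           motif_id="MOTIF_ETS", motif_prob=0.6),
        ),
        seed=config.seed + 3,
    )
    bundle = sim.simulate_atac(aconfig)
    counts, meta = bundle["counts"], bundle["sample_meta"]
    meta = atac.frip_filter(meta, thr.frip_min)
    counts = counts[meta["sample_id"]]
    lengths = pd.Series(
        (bundle["regions"]["end"] - bundle["regions"]["start"]).to_numpy(),
        index=bundle["regions"]["region_id"],
    )
    found_in, retained = atac.presence_filter(
        counts, lengths, meta, min_fpkm=thr.fpkm_presence_min,
        fraction=thr.presence_fraction,
    )
    counts = counts.loc[retained]
    io.write_bed(bundle["regions"], outdir / "peaks.bed")
    _write(meta, outdir, "atac_sample_sheet.tsv", config)

    dar_minus = atac.dar_test(counts, meta, {"population": "CD49b-", "age_group": "O"},
                              {"population": "CD49b-", "age_group": "J"},
                              found_in=found_in)
    dar_plus = atac.dar_test(counts, meta, {"population": "CD49b+", "age_group": "O"},
                             {"population": "CD49b+", "age_group": "J"},
                             found_in=found_in)
    dar_lineage = atac.dar_test(counts, meta,
                                {"population": "CD49b+", "age_group": "J"},
                                {"population": "CD49b-", "age_group": "O"},
                                found_in=found_in)
    _write(dar_minus, outdir, "dars_aging_CD49bneg.tsv", config, index=True)
    _write(dar_plus, outdir, "dars_aging_CD49bpos.tsv", config, index=True)
    _write(dar_lineage, outdir, "dars_lineage.tsv", config, index=True)
    report["dars"] = {"aging_minus": dar_minus, "aging_plus": dar_plus,
                      "lineage": dar_lineage}

    aging_union = atac.significant_regions(dar_minus, thr.p_adj_aging).union(
        atac.significant_regions(dar_plus, thr.p_adj_aging)
    )
    rip = meta.set_index("sample_id")["reads_in_peaks"]
    norm = atac.normalize_counts(counts, rip)
    logq = atac.log_quantile_normalize(norm)
    sample_groups = meta.set_index("sample_id")["group"]
    if len(aging_union) >= 3:
        labels, medians = atac.cluster_dars(logq.loc[aging_union], k=3,
                                            sample_groups=sample_groups)
        _write(labels.to_frame(), outdir, "aging_dar_clusters.tsv", config, index=True)
        open_frac = atac.open_fraction(labels, found_in)
        _write(open_frac, outdir, "aging_dar_open_fraction.tsv", config, index=True)
        report["aging_clusters"] = labels
        report["open_fraction"] = open_frac

    lin = atac.lin_dars(dar_lineage, [dar_minus, dar_plus],
                        lineage_p_adj=thr.p_adj_subset,
                        aging_p_adj=thr.p_adj_aging)
    report["lin_dars"] = lin
    lin_frame = pd.DataFrame({"region_id": lin})
    if len(lin) >= 2:
        lin_labels, _ = atac.cluster_dars(logq.loc[lin], k=2,
                                          sample_groups=sample_groups)
        lin_frame["cluster"] = lin_labels.to_numpy()
    _write(lin_frame, outdir, "lin_dars.tsv", config)

    sequences = bundle["sequences"]
    target = {r: sequences[r] for r in lin} if len(lin) else {}
    background_ids = [r for r in counts.index if r not in set(lin)]
    background = {r: sequences[r] for r in background_ids}
    if target:
        enrich = atac.motif_enrichment_table(target, background,
                                             aconfig.motif_pfms)
        _write(enrich, outdir, "lin_dar_motif_enrichment.tsv", config)
        report["motif_enrichment"] = enrich

    truth_atac = bundle["truth"].set_index("region_id")
    planted_aging = truth_atac.index[truth_atac["planted_set"] == "aging_gain"]
    tested = planted_aging.intersection(dar_minus.index)
    sens = float((dar_minus.loc[tested, "p_adj"] < thr.p_adj_aging).mean()) \
        if len(tested) else np.nan
    null_regions = truth_atac.index[truth_atac["planted_set"] == "none"]
    null_tested = null_regions.intersection(dar_minus.index)
    sig_null = int((dar_minus.loc[null_tested, "p_adj"] < thr.p_adj_aging).sum())
    audit.update({
        "aging_dar_sensitivity": sens,
        "aging_dar_false_positives": sig_null,
        "n_lin_dars": int(len(lin)),
    })

    # --- single-cell expression --------------------------------------------
    logger.info("stage sc_expression: %d cells/group", config.sc_cells_per_group)
    n_sig = 40
    scconfig = sim.ScSimConfig(
        n_cells_per_group=config.sc_cells_per_group,
        n_genes=config.sc_n_genes,
        signature_sets=(
            sim.SignatureSet("proliferation", tuple(range(n_sig)),
                             {"CD49b-": 0.5}),
            sim.SignatureSet("quiescence", tuple(range(n_sig, 2 * n_sig)),
                             {"CD49b+": 0.5}),
        ),
        seed=config.seed + 4,
    )
    adata, sc_truth = sim.simulate_cells(scconfig)
    filtered, rejection_log = scx.qc_filter(adata)
    _write(rejection_log, outdir, "sc_qc_rejections.tsv", config)
    filtered = scx.gene_filter(filtered)
    filtered = scx.normalize(filtered)
    prolif_genes = [f"gene_{j:04d}" for j in range(n_sig)]
    scores = scx.module_score(filtered, prolif_genes, seed=config.seed)
    score_table = pd.DataFrame({
        "cell_id": scores.index, "score": scores.to_numpy(),
        "gene_set": "proliferation",
        "group": filtered.obs["group"].to_numpy(),
    })
    _write(score_table, outdir, "sc_module_scores.tsv", config)
    report["module_scores"] = score_table
    deg = scx.differential_expression_lr(filtered, "group", "CD49b-", "CD49b+")
    _write(deg, outdir, "sc_deg.tsv", config)
    report["deg"] = deg
    score_shift = float(
        score_table.loc[score_table["group"] == "CD49b-", "score"].mean()
        - score_table.loc[score_table["group"] == "CD49b+", "score"].mean()
    )
    audit["module_score_shift"] = score_shift
    audit["n_deg_significant"] = int(len(scx.significant_genes(
        deg, thr.p_adj_deg, thr.min_abs_log2fc_deg)))

    audit_df = pd.DataFrame(sorted(audit.items()), columns=["metric", "value"])
    _write(audit_df, outdir, "ground_truth_audit.tsv", config)
    report["audit"] = audit

    summary_lines = [f"hscfate run summary (seed={config.seed}, "
                     f"config={config.config_hash()})"]
    summary_lines += [f"  {k} = {v}" for k, v in sorted(audit.items())]
    (outdir / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    (outdir / "run_config.yaml").write_text(config.to_yaml())
    return report
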