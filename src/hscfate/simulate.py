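"""Seeded synthetic-data generators with planted ground truth.

Every input the analysis modules consume can be generated here with known
truth, enabling parameter-recovery tests: clone-level transplantation
outcomes with age- and subset-dependent bias-archetype mixtures,
negative-binomial ATAC-seq count matrices with planted differential
regions and motif occurrences, unmanipulated reference blood cohorts, and
single-cell count matrices with planted signature shifts and QC-failure
cells.

All generators are bit-reproducible under a fixed seed; compositional
draws (lineage fractions) sum to 1 to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

from .repopulation import LEUKOCYTE_LINEAGES

ARCHETYPES = ("M-bi", "Bal", "L-bi")

#: Dirichlet means over (B, T, NK, myeloid) per repopulation archetype.
DEFAULT_ARCHETYPE_MEANS = {
    "M-bi": (0.15, 0.05, 0.05, 0.75),
    "Bal": (0.40, 0.15, 0.05, 0.40),
    "L-bi": (0.65, 0.20, 0.05, 0.10),
}

#: archetype mixture per (age_group, subset); juvenile/adult CD49b- mice are
#: mostly myeloid-biased and CD49b+ mostly lymphoid-biased, while in old mice
#: both subsets shift myeloid-ward with CD49b+ enriching balanced output.
DEFAULT_ARCHETYPE_MIX = {
    ("J", "CD49b-"): {"M-bi": 0.55, "Bal": 0.30, "L-bi": 0.15},
    ("J", "CD49b+"): {"M-bi": 0.20, "Bal": 0.30, "L-bi": 0.50},
    ("A", "CD49b-"): {"M-bi": 0.55, "Bal": 0.30, "L-bi": 0.15},
    ("A", "CD49b+"): {"M-bi": 0.20, "Bal": 0.30, "L-bi": 0.50},
    ("O", "CD49b-"): {"M-bi": 0.75, "Bal": 0.20, "L-bi": 0.05},
    ("O", "CD49b+"): {"M-bi": 0.35, "Bal": 0.55, "L-bi": 0.10},
}

#: transplanted HSC dose per age group (limiting dose for young donors, one
#: hundred cells for old donors to offset reduced regenerative capacity)
DEFAULT_DOSE = {"J": 5, "A": 5, "O": 100}

#: unmanipulated peripheral-blood composition (B, T, NK, myeloid); old mice
#: skew myeloid
REFERENCE_COMPOSITION = {
    "adult": (0.40, 0.15, 0.05, 0.40),
    "old": (0.25, 0.10, 0.05, 0.60),
}


class ConfigurationError(ValueError):
    pass


def _check_probability(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must be in [0, 1], got {value}")


@dataclass
class TransplantSimConfig:
    """Study conditions for the competitive-transplantation simulator."""

    n_mice_per_group: int = 20
    groups: tuple = tuple(DEFAULT_ARCHETYPE_MIX)
    dose: dict = field(default_factory=lambda: dict(DEFAULT_DOSE))
    engraftment_prob: float = 0.1
    archetype_mix: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_ARCHETYPE_MIX.items()
    })
    archetype_means: dict = field(default_factory=lambda: {
        k: tuple(v) for k, v in DEFAULT_ARCHETYPE_MEANS.items()
    })
    dirichlet_concentration: float = 100.0
    chimerism_mean: float = 0.3
    chimerism_noise: float = 0.02  # inverse Beta concentration
    timepoints: tuple = (2, 6)
    total_events_per_lineage: int = 20_000
    host_composition: tuple = REFERENCE_COMPOSITION["adult"]
    seed: int = 0

    def __post_init__(self):
        _check_probability("engraftment_prob", self.engraftment_prob)
        _check_probability("chimerism_mean", self.chimerism_mean)
        for group, mix in self.archetype_mix.items():
            total = sum(mix.values())
            for name, p in mix.items():
                _check_probability(f"archetype_mix[{group}][{name}]", p)
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"archetype_mix[{group}] sums to {total}, expected 1"
                )
        for name, mean in self.archetype_means.items():
            if abs(sum(mean) - 1.0) > 1e-9:
                raise ConfigurationError(f"archetype mean {name} must sum to 1")
        for age, d in self.dose.items():
            if d < 1:
                raise ConfigurationError(f"dose[{age}] must be >= 1")
        if self.dirichlet_concentration <= 0 or self.chimerism_noise <= 0:
            raise ConfigurationError("concentration parameters must be positive")


def simulate_transplants(config: TransplantSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-mouse peripheral-blood/bone-marrow event tables plus ground truth.

    Each mouse engrafts ``Poisson(dose * engraftment_prob)`` clones; every
    clone draws a bias archetype from its group's mixture and lineage
    fractions from a Dirichlet around the archetype mean. The mouse's donor
    composition is a convex combination of its clones (Dirichlet(1) clone
    weights); the recorded dominant archetype is that of the largest-weight
    clone. Non-engrafted mice show only uniform background donor signal
    below the 0.1% positivity threshold.
    """
    rng = np.random.default_rng(config.seed)
    means = {k: np.asarray(v, float) for k, v in config.archetype_means.items()}
    host = np.asarray(config.host_composition, float)
    n_per = config.total_events_per_lineage
    measurements, truth = [], []
    for age_group, subset in config.groups:
        mix = config.archetype_mix[(age_group, subset)]
        mix_names = sorted(mix)
        mix_p = np.array([mix[a] for a in mix_names])
        dose = config.dose[age_group]
        for m in range(config.n_mice_per_group):
            mouse_id = f"{age_group}_{subset}_m{m:03d}"
            group = f"{age_group}:{subset}"
            n_clones = int(rng.poisson(dose * config.engraftment_prob))
            if n_clones == 0:
                truth.append({
                    "mouse_id": mouse_id, "group": group, "age_group": age_group,
                    "subset": subset, "n_clones": 0, "dominant_archetype": "none",
                    "chimerism": 0.0,
                    **{f"true_frac_{ln}": np.nan for ln in LEUKOCYTE_LINEAGES},
                })
                measurements.extend(
                    _background_rows(rng, mouse_id, group, config.timepoints, n_per)
                )
                continue
            archetypes = [mix_names[i] for i in rng.choice(len(mix_names),
                                                           size=n_clones, p=mix_p)]
            clone_fracs = np.vstack([
                rng.dirichlet(config.dirichlet_concentration * means[a])
                for a in archetypes
            ])
            weights = rng.dirichlet(np.ones(n_clones))
            fractions = weights @ clone_fracs
            dominant = archetypes[int(np.argmax(weights))]
            kappa = 1.0 / config.chimerism_noise
            chimerism = float(rng.beta(config.chimerism_mean * kappa,
                                       (1 - config.chimerism_mean) * kappa))
            chimerism = min(max(chimerism, 1e-4), 0.999)
            truth.append({
                "mouse_id": mouse_id, "group": group, "age_group": age_group,
                "subset": subset, "n_clones": n_clones,
                "dominant_archetype": dominant, "chimerism": chimerism,
                **{f"true_frac_{ln}": fractions[i]
                   for i, ln in enumerate(LEUKOCYTE_LINEAGES)},
            })
            measurements.extend(_engrafted_rows(
                rng, mouse_id, group, config.timepoints, n_per, chimerism,
                fractions, host,
            ))
    pb = pd.DataFrame(measurements)
    pb["donor_frequency"] = 100.0 * pb["donor_events"] / pb["total_events"]
    return pb, pd.DataFrame(truth)


def _row(mouse_id, group, t, compartment, lineage, donor, total):
    return {"mouse_id": mouse_id, "group": group, "timepoint_months": t,
            "compartment": compartment, "lineage": lineage,
            "donor_events": int(donor), "total_events": int(total)}


def _background_rows(rng, mouse_id, group, timepoints, n_per):
    """Donor signal for a non-engrafted mouse: uniform noise below 0.1%."""
    rows = []
    for t in timepoints:
        for lineage, total in [("leukocyte_total", 4 * n_per), ("platelet", n_per),
                               *[(ln, n_per) for ln in LEUKOCYTE_LINEAGES]]:
            u = rng.uniform(0.0, 0.0009)
            rows.append(_row(mouse_id, group, t, "PB", lineage,
                             int(np.floor(u * total)), total))
        for lineage in ("BM_lymphoid", "BM_myeloid", "HSC"):
            u = rng.uniform(0.0, 0.0009)
            total = 2000 if lineage == "HSC" else n_per
            rows.append(_row(mouse_id, group, t, "BM", lineage,
                             int(np.floor(u * total)), total))
    return rows


def _engrafted_rows(rng, mouse_id, group, timepoints, n_per, chimerism,
                    fractions, host):
    rows = []
    blood_mix = chimerism * fractions + (1 - chimerism) * host
    blood_mix = blood_mix / blood_mix.sum()
    donor_within = chimerism * fractions / blood_mix
    for t in timepoints:
        n_total = 4 * n_per
        rows.append(_row(mouse_id, group, t, "PB", "leukocyte_total",
                         rng.binomial(n_total, chimerism), n_total))
        rows.append(_row(mouse_id, group, t, "PB", "platelet",
                         rng.binomial(n_per, chimerism), n_per))
        lineage_totals = rng.multinomial(n_total, blood_mix)
        for i, ln in enumerate(LEUKOCYTE_LINEAGES):
            donor = rng.binomial(lineage_totals[i], min(donor_within[i], 1.0))
            rows.append(_row(mouse_id, group, t, "PB", ln, donor,
                             lineage_totals[i]))
        l_frac = fractions[:3].sum()
        rows.append(_row(mouse_id, group, t, "BM", "BM_lymphoid",
                         rng.binomial(n_per, chimerism * l_frac), n_per))
        rows.append(_row(mouse_id, group, t, "BM", "BM_myeloid",
                         rng.binomial(n_per, chimerism * fractions[3]), n_per))
        rows.append(_row(mouse_id, group, t, "BM", "HSC",
                         rng.binomial(2000, chimerism), 2000))
    return rows


def simulate_reference_cohort(
    age_group: str,
    n_mice: int,
    seed: int,
    concentration: float = 100.0,
) -> pd.DataFrame:
    """Peripheral-blood lineage fractions for unmanipulated mice.

    ``age_group`` is 'adult' or 'old'; the old cohort mean is shifted
    myeloid-ward. Returns one row per mouse with B/T/NK/myeloid fractions
    and the L/M ratio.
    """
    if age_group not in REFERENCE_COMPOSITION:
        raise ConfigurationError(f"age_group must be one of {list(REFERENCE_COMPOSITION)}")
    if n_mice < 2:
        raise ConfigurationError("reference cohort needs at least 2 mice")
    rng = np.random.default_rng(seed)
    mean = np.asarray(REFERENCE_COMPOSITION[age_group], float)
    fracs = rng.dirichlet(concentration * mean, size=n_mice)
    df = pd.DataFrame(fracs, columns=list(LEUKOCYTE_LINEAGES))
    df.insert(0, "mouse_id", [f"{age_group}_ref_m{i:03d}" for i in range(n_mice)])
    with np.errstate(divide="ignore"):
        df["lm_ratio"] = fracs[:, :3].sum(axis=1) / fracs[:, 3]
    return df


# ---------------------------------------------------------------------------
# ATAC-seq simulator
# ---------------------------------------------------------------------------

#: small synthetic motif library (consensus strings)
DEFAULT_MOTIF_CONSENSUS = {
    "MOTIF_GATA": "AGATAAGA",
    "MOTIF_ETS": "ACAGGAAGTG",
    "MOTIF_KLF": "GGGGCGGGGC",
    "MOTIF_RUNX": "TGTGGTTT",
}


def consensus_to_pfm(consensus: str, strength: float = 0.97) -> np.ndarray:
    """4 x L frequency matrix concentrated on a consensus sequence."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(consensus)
    pfm = np.full((4, L), (1 - strength) / 3)
    for j, b in enumerate(consensus.upper()):
        pfm[idx[b], j] = strength
    return pfm


def default_motif_pfms() -> dict[str, np.ndarray]:
    return {k: consensus_to_pfm(v) for k, v in DEFAULT_MOTIF_CONSENSUS.items()}


@dataclass
class PlantedSet:
    """A named set of regions with per-group log2 effects and optional motif."""

    name: str
    n_regions: int
    log2fc_by_group: dict = field(default_factory=dict)  # group label -> log2FC
    motif_id: str | None = None
    motif_prob: float = 0.0


@dataclass
class AtacSimConfig:
    n_regions: int = 2000
    region_length_bp: int = 300
    groups: tuple = (("CD49b-", "J"), ("CD49b-", "O"))
    n_samples_per_group: int = 5
    baseline_log_mean: float = 4.0  # natural-log mean of per-region count rate
    baseline_log_sd: float = 1.0
    dispersion: float = 0.1  # NB alpha: var = mu + alpha mu^2
    planted_sets: tuple = ()
    library_size_range: tuple = (0.7, 1.3)
    allow_overlapping_sets: bool = False
    motif_pfms: dict = field(default_factory=default_motif_pfms)
    seed: int = 0

    def __post_init__(self):
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        for ps in self.planted_sets:
            if ps.n_regions > self.n_regions:
                raise ConfigurationError(f"planted set {ps.name} too large")
            _check_probability(f"motif_prob[{ps.name}]", ps.motif_prob)


def _group_label(population: str, age_group: str) -> str:
    return f"{population}:{age_group}"


def simulate_atac(config: AtacSimConfig) -> dict:
    """NB-distributed region-by-sample accessibility counts with planted truth.

    Returns a dict with ``counts`` (regions x samples), ``sample_meta``,
    ``regions`` (BED-like frame), ``sequences`` (region_id -> sequence),
    and ``truth`` (per-region planted set membership and effects).
    Planted sets receive disjoint region indices (front-to-back) unless
    overlap is explicitly allowed.
    """
    rng = np.random.default_rng(config.seed)
    R = config.n_regions
    region_ids = [f"region_{i:05d}" for i in range(R)]
    # assign planted set indices
    cursor = 0
    set_indices: dict[str, np.ndarray] = {}
    for ps in config.planted_sets:
        if config.allow_overlapping_sets:
            idx = rng.choice(R, size=ps.n_regions, replace=False)
        else:
            if cursor + ps.n_regions > R:
                raise ConfigurationError("planted sets exceed region count")
            idx = np.arange(cursor, cursor + ps.n_regions)
            cursor += ps.n_regions
        set_indices[ps.name] = idx
    if not config.allow_overlapping_sets:
        all_idx = np.concatenate([v for v in set_indices.values()]) if set_indices else []
        if len(all_idx) != len(set(map(int, all_idx))):
            raise ConfigurationError("planted sets overlap")

    group_labels = [_group_label(p, a) for p, a in config.groups]
    samples, sample_group = [], []
    for (pop, age), label in zip(config.groups, group_labels):
        for s in range(config.n_samples_per_group):
            samples.append(f"{pop}_{age}_s{s}")
            sample_group.append((pop, age, label))
    S = len(samples)
    log_mu = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=R)
    lib = rng.uniform(*config.library_size_range, size=S)
    log2_effect = np.zeros((R, S))
    for ps in config.planted_sets:
        for glabel, lfc in ps.log2fc_by_group.items():
            cols = [j for j, (_, _, lbl) in enumerate(sample_group) if lbl == glabel]
            log2_effect[np.ix_(set_indices[ps.name], cols)] += lfc
    mu = np.exp(log_mu)[:, None] * lib[None, :] * 2.0 ** log2_effect
    r = 1.0 / config.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=region_ids, columns=samples)

    reads_in_peaks = counts_df.sum(axis=0)
    sample_meta = pd.DataFrame({
        "sample_id": samples,
        "population": [g[0] for g in sample_group],
        "age_group": [g[1] for g in sample_group],
        "group": [g[2] for g in sample_group],
        "frip": rng.uniform(0.2, 0.6, size=S),
        "reads_in_peaks": reads_in_peaks.to_numpy(),
    })
    length = config.region_length_bp
    regions = pd.DataFrame({
        "chrom": ["chr1"] * R,
        "start": np.arange(R) * (length + 700),
        "end": np.arange(R) * (length + 700) + length,
        "region_id": region_ids,
    })
    # sequences: i.i.d. uniform nucleotides with planted exact consensus
    bases = np.array(list("ACGT"))
    seq_arr = rng.integers(0, 4, size=(R, length))
    planted_motifs = {}
    for ps in config.planted_sets:
        if ps.motif_id is None or ps.motif_prob == 0:
            continue
        consensus = DEFAULT_MOTIF_CONSENSUS.get(ps.motif_id)
        if consensus is None:
            raise ConfigurationError(f"unknown motif {ps.motif_id}")
        enc = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in consensus])
        for i in set_indices[ps.name]:
            if rng.uniform() < ps.motif_prob:
                pos = int(rng.integers(0, length - len(enc) + 1))
                seq_arr[i, pos : pos + len(enc)] = enc
                planted_motifs[region_ids[i]] = (ps.motif_id, pos)
    sequences = {rid: "".join(bases[row]) for rid, row in zip(region_ids, seq_arr)}

    truth = pd.DataFrame({"region_id": region_ids, "planted_set": "none"})
    truth = truth.set_index("region_id")
    for ps in config.planted_sets:
        truth.loc[[region_ids[i] for i in set_indices[ps.name]], "planted_set"] = ps.name
        for glabel, lfc in ps.log2fc_by_group.items():
            col = f"log2fc_{glabel}"
            if col not in truth:
                truth[col] = 0.0
            truth.loc[[region_ids[i] for i in set_indices[ps.name]], col] = lfc
    truth["planted_motif"] = [
        planted_motifs.get(rid, (None, -1))[0] for rid in truth.index
    ]
    return {
        "counts": counts_df,
        "sample_meta": sample_meta,
        "regions": regions,
        "sequences": sequences,
        "truth": truth.reset_index(),
    }


# ---------------------------------------------------------------------------
# single-cell simulator
# ---------------------------------------------------------------------------

@dataclass
class SignatureSet:
    """Gene-index set with per-group shifts in log expression (natural log)."""

    name: str
    gene_indices: tuple
    shifts: dict = field(default_factory=dict)  # group -> log shift


@dataclass
class ScSimConfig:
    n_cells_per_group: int = 250
    groups: tuple = ("CD49b-", "CD49b+")
    n_genes: int = 2000
    signature_sets: tuple = ()
    depth_lognormal_params: tuple = (np.log(150_000), 0.25)
    mito_beta_params: tuple = (2.0, 38.0)
    ercc_beta_params: tuple = (2.0, 38.0)
    fail_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.fail_fraction < 1:
            raise ConfigurationError("fail_fraction must be in [0, 1)")
        for ss in self.signature_sets:
            if max(ss.gene_indices, default=-1) >= self.n_genes:
                raise ConfigurationError(
                    f"signature {ss.name} indexes beyond n_genes"
                )


def simulate_cells(config: ScSimConfig) -> tuple[AnnData, pd.DataFrame]:
    """Cell-by-gene counts with planted signature shifts and QC failures.

    Exactly ``round(fail_fraction * n_cells)`` cells are forced to violate
    one QC clause (low/high reads, high mito, or high ERCC, cycling); all
    other cells are guaranteed to pass. Signature genes are drawn from the
    well-expressed tail so that log-scale shifts survive normalization.
    Returns (AnnData with counts and metadata, ground-truth cell table).
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    sig_genes = sorted({i for ss in config.signature_sets for i in ss.gene_indices})
    base = rng.lognormal(0.0, 1.0, size=G)
    base[sig_genes] = rng.lognormal(2.0, 0.5, size=len(sig_genes))
    n_total = config.n_cells_per_group * len(config.groups)
    cell_groups = np.repeat(list(config.groups), config.n_cells_per_group)
    cell_ids = [f"cell_{i:04d}" for i in range(n_total)]

    n_fail = round(config.fail_fraction * n_total)
    fail_cells = rng.choice(n_total, size=n_fail, replace=False)
    fail_clause = {}
    clauses = ["low_reads", "high_reads", "high_mito", "high_ercc"]
    for k, c in enumerate(fail_cells):
        fail_clause[c] = clauses[k % len(clauses)]

    mu_log, sd_log = config.depth_lognormal_params
    counts = np.zeros((n_total, G), dtype=np.int64)
    meta = []
    for i in range(n_total):
        clause = fail_clause.get(i)
        mito = float(np.clip(rng.beta(*config.mito_beta_params), 0, 0.095))
        ercc = float(np.clip(rng.beta(*config.ercc_beta_params), 0, 0.095))
        total_reads = float(np.clip(rng.lognormal(mu_log, sd_log), 60_000, 700_000))
        if clause == "low_reads":
            total_reads = rng.uniform(10_000, 45_000)
        elif clause == "high_reads":
            total_reads = rng.uniform(800_000, 1_200_000)
        elif clause == "high_mito":
            mito = rng.uniform(0.10, 0.30)
        elif clause == "high_ercc":
            ercc = rng.uniform(0.10, 0.30)
        rates = base.copy()
        for ss in config.signature_sets:
            shift = ss.shifts.get(cell_groups[i], 0.0)
            if shift:
                rates[list(ss.gene_indices)] *= np.exp(shift)
        p = rates / rates.sum()
        gene_depth = int(round(total_reads * (1 - mito - ercc)))
        counts[i] = rng.multinomial(gene_depth, p)
        meta.append({
            "cell_id": cell_ids[i], "group": cell_groups[i],
            "total_reads": int(round(total_reads)), "mito_fraction": mito,
            "ercc_fraction": ercc,
            "qc_fail_planted": clause is not None,
            "fail_clause": clause or "",
        })
    obs = pd.DataFrame(meta).set_index("cell_id")
    var = pd.DataFrame(index=[f"gene_{j:04d}" for j in range(G)])
    adata = AnnData(X=counts, obs=obs, var=var)
    truth = obs[["group", "qc_fail_planted", "fail_clause"]].reset_index()
    return adata, truth
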