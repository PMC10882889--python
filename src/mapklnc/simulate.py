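"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates one class of raw data the pipeline consumes:

* :func:`gen_annotation` — a reference annotation plus an "assembled"
  transcript set containing planted novel multi-exonic lncRNAs, structural
  noise (each noise transcript violates exactly one discovery filter) and
  reference-overlapping transcripts, with per-transcript sequences.
* :func:`gen_expression_cohorts` — log-normal FPKM matrices for several
  conditions with sign-consistent planted DE genes across the configured
  comparisons, and one gene pair with a target Spearman correlation
  planted through a Gaussian copula.
* :func:`gen_kinase_plate` — a 384-well-style plate with ATP standards,
  all three control classes, and treatment effects planted as
  multiplicative changes of per-peptide ATP consumption.
* :func:`gen_viability_grid` — dose-pair survivals equal to the product of
  exponential single-agent survivals times 2^(bliss_deviation).
* :func:`gen_ct_table` — qPCR Ct values encoding known fold changes
  (ΔΔCt = −log2(fold)) and known nuclear/cytoplasmic ratios.

All randomness flows from ``SimConfig.seed`` through a fixed
``SeedSequence`` spawn order, so identical configs give byte-identical
artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, TranscriptModel
from .expression import ExpressionMatrix
from .kinome import PlateAssay
from .pharm import CtTable, ViabilityGrid

__all__ = [
    "SimConfig",
    "GroundTruth",
    "AnnotationBundle",
    "gen_annotation",
    "gen_expression_cohorts",
    "build_plate_layout",
    "default_kinase_map",
    "gen_kinase_plate",
    "gen_viability_grid",
    "gen_ct_table",
]

_DEFAULT_COMPARISONS = (("PHM_E", "PHM_Q61"), ("PHM", "D04"), ("PHM", "MM415"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic datasets.

    Defaults mirror the experimental design the pipeline targets: five
    melanocyte/melanoma conditions with six replicates each compared in
    three wild-type-vs-mutant pairs, a 2-log2 planted fold change with
    0.3 log2 units of expression noise, a planted Spearman 0.4 gene pair,
    a kinase whose activity halves under treatment, and a synergistic
    drug combination 0.5 log2 units below Bliss independence.
    """

    seed: int = 0
    # annotation
    n_reference_genes: int = 50
    n_planted_lncrna: int = 5
    n_noise_transcripts: int = 30
    chrom: str = "chrS"
    chrom_length: int = 10_000_000
    # expression cohorts
    n_genes: int = 2000
    cohort_sizes: Dict[str, int] = field(
        default_factory=lambda: {c: 6 for c in ("PHM", "PHM_E", "PHM_Q61", "D04", "MM415")}
    )
    comparisons: Tuple[Tuple[str, str], ...] = _DEFAULT_COMPARISONS
    n_planted_up: int = 20
    n_planted_down: int = 20
    planted_log2fc: float = 2.0
    planted_rho: float = 0.4
    noise_sd: float = 0.3  # log2 units
    # kinase plate
    plate_effect: Dict[str, float] = field(default_factory=lambda: {"K1": 0.5})
    plate_noise_cv: float = 0.02
    # drug combination
    bliss_deviation: float = -0.5  # log2 units
    viability_noise_cv: float = 0.02

    def __post_init__(self) -> None:
        counts = (
            self.n_reference_genes,
            self.n_planted_lncrna,
            self.n_noise_transcripts,
            self.n_genes,
            self.n_planted_up,
            self.n_planted_down,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.chrom_length <= 0:
            raise ValueError("chromosome length must be positive")
        if abs(self.planted_rho) > 1:
            raise ValueError("|planted_rho| must be <= 1")
        for cond, n in self.cohort_sizes.items():
            if n < 2:
                raise ValueError(f"cohort {cond!r} needs >= 2 samples")

    def _rngs(self, n: int, stream: int) -> List[np.random.Generator]:
        """Independent generators for one artifact family (fixed spawn order)."""
        children = np.random.SeedSequence([self.seed, stream]).spawn(n)
        return [np.random.default_rng(s) for s in children]


@dataclass
class GroundTruth:
    planted_novel_lncrna_ids: List[str] = field(default_factory=list)
    planted_de_ids_by_direction: Dict[str, List[str]] = field(
        default_factory=lambda: {"up": [], "down": []}
    )
    correlated_pair: Optional[Tuple[str, str]] = None
    kinase_effects: Dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Annotation bundle


@dataclass
class AnnotationBundle:
    reference: AnnotationSet
    assembled: AnnotationSet
    sequences: Dict[str, str]  # per assembled transcript
    truth: GroundTruth


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _scrub_start_codons(seq: str) -> str:
    """Remove ATG on both strands (reverse-strand ATG reads CAT forward),
    leaving no open reading frame in any of the six frames."""
    while "ATG" in seq or "CAT" in seq:
        seq = seq.replace("ATG", "ACG").replace("CAT", "CAC")
    return seq


def gen_annotation(config: SimConfig) -> AnnotationBundle:
    """Reference + assembled annotation with planted novel lncRNAs.

    The assembled set contains, in disjoint 20-kb slots along one synthetic
    chromosome: one transcript overlapping each reference gene (removed by
    the novelty filter), the planted lncRNAs (3 exons of 150 nt, 50-bp
    introns, start-codon-free sequence → classified ncRNA), and noise
    transcripts cycling through the three structural-violation classes
    (mono-exonic; total length exactly 200 nt; all introns exactly 10 bp).
    """
    slot = 20_000
    n_slots = config.n_reference_genes + config.n_planted_lncrna + config.n_noise_transcripts
    if n_slots * slot > config.chrom_length:
        raise ValueError(
            f"chromosome of {config.chrom_length} bp cannot hold {n_slots} features"
        )
    rng_seq, rng_place = config._rngs(2, stream=0)
    strands = ["+", "-"]

    reference: List[TranscriptModel] = []
    assembled: List[TranscriptModel] = []
    sequences: Dict[str, str] = {}
    truth = GroundTruth()

    slot_starts = [1 + i * slot for i in range(n_slots)]
    cursor = 0

    # reference genes + one assembled transcript overlapping each
    for i in range(config.n_reference_genes):
        base = slot_starts[cursor]; cursor += 1
        strand = strands[i % 2]
        ref = TranscriptModel(
            transcript_id=f"REF_T{i + 1:04d}",
            gene_id=f"REFG{i + 1:04d}",
            chrom=config.chrom,
            strand=strand,
            exons=((base, base + 499), (base + 700, base + 1199)),
        )
        reference.append(ref)
        over = TranscriptModel(
            transcript_id=f"ASM_KNOWN{i + 1:04d}",
            gene_id=f"ASM_KNOWN{i + 1:04d}",
            chrom=config.chrom,
            strand=strand,
            exons=((base + 200, base + 899), (base + 1000, base + 1399)),
        )
        assembled.append(over)
        sequences[over.transcript_id] = _random_seq(rng_seq, over.length)

    # planted novel lncRNAs: 3 × 150-nt exons, 50-bp introns → length 450 > 200
    for i in range(config.n_planted_lncrna):
        base = slot_starts[cursor]; cursor += 1
        tid = f"LNC_NOVEL{i + 1:04d}"
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=tid,
            chrom=config.chrom,
            strand=strands[i % 2],
            exons=(
                (base, base + 149),
                (base + 200, base + 349),
                (base + 400, base + 549),
            ),
        )
        assembled.append(t)
        sequences[tid] = _scrub_start_codons(_random_seq(rng_seq, t.length))
        truth.planted_novel_lncrna_ids.append(tid)

    # structural noise: each violates exactly one filter
    for i in range(config.n_noise_transcripts):
        base = slot_starts[cursor]; cursor += 1
        kind = i % 3
        tid = f"NOISE{i + 1:04d}"
        if kind == 0:  # mono-exonic, otherwise long
            exons = ((base, base + 4999),)
        elif kind == 1:  # multi-exonic but exactly 200 nt total (not > 200)
            exons = ((base, base + 99), (base + 150, base + 249))
        else:  # multi-exonic, long, but all introns exactly 10 bp
            exons = ((base, base + 199), (base + 210, base + 409))
        t = TranscriptModel(
            transcript_id=tid, gene_id=tid, chrom=config.chrom,
            strand=strands[i % 2], exons=exons,
        )
        assembled.append(t)
        sequences[tid] = _random_seq(rng_seq, t.length)

    return AnnotationBundle(
        reference=AnnotationSet(reference),
        assembled=AnnotationSet(assembled),
        sequences=sequences,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Expression cohorts


def gen_expression_cohorts(
    config: SimConfig,
) -> Tuple[Dict[str, ExpressionMatrix], GroundTruth]:
    """Log-normal FPKM matrices per condition with planted DE and a planted
    correlated pair.

    Baseline per-gene abundance is log-uniform over roughly 1–100 FPKM;
    samples add Gaussian noise of ``noise_sd`` log2 units. Planted up/down
    genes are shifted by ±``planted_log2fc`` in the case condition of every
    configured comparison (the same sign everywhere). The last two genes
    form the correlated pair: their log-abundances are a bivariate normal
    with Pearson r = 2·sin(π·ρ/6), the copula value for Spearman ρ; this
    pair keeps unit log2 variance so its rank correlation is defined even
    at zero expression noise.
    """
    n_special = 2
    if config.n_planted_up + config.n_planted_down + n_special > config.n_genes:
        raise ValueError("too many planted genes for n_genes")
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    up_ids = genes[: config.n_planted_up]
    down_ids = genes[config.n_planted_up : config.n_planted_up + config.n_planted_down]
    pair = (genes[-2], genes[-1])

    case_conditions = {b for _, b in config.comparisons}
    conditions = list(config.cohort_sizes)
    rngs = config._rngs(1 + len(conditions), stream=1)
    base_rng, cond_rngs = rngs[0], rngs[1:]

    baseline = base_rng.uniform(0.0, np.log2(100.0), size=config.n_genes)
    r_pearson = 2.0 * np.sin(np.pi * config.planted_rho / 6.0)

    up_idx = np.arange(config.n_planted_up)
    down_idx = np.arange(
        config.n_planted_up, config.n_planted_up + config.n_planted_down
    )

    matrices: Dict[str, ExpressionMatrix] = {}
    for cond, rng in zip(conditions, cond_rngs):
        n = config.cohort_sizes[cond]
        log2x = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
        if cond in case_conditions:
            log2x[up_idx] += config.planted_log2fc
            log2x[down_idx] -= config.planted_log2fc
        # correlated pair: bivariate-normal copula on the log scale
        z1 = rng.standard_normal(n)
        w = rng.standard_normal(n)
        z2 = r_pearson * z1 + np.sqrt(max(1.0 - r_pearson**2, 0.0)) * w
        log2x[-2] = baseline[-2] + z1
        log2x[-1] = baseline[-1] + z2

        samples = [f"{cond}_s{j + 1:03d}" for j in range(n)]
        meta = pd.DataFrame(
            {
                "condition": cond,
                "patient_id": [f"{cond}_p{j + 1:03d}" for j in range(n)],
                "specimen_order": 1,
            },
            index=pd.Index(samples, name="sample_id"),
        )
        matrices[cond] = ExpressionMatrix(
            values=pd.DataFrame(2.0**log2x, index=pd.Index(genes, name="gene_id"), columns=samples),
            unit="FPKM",
            sample_meta=meta,
        )

    truth = GroundTruth(
        planted_de_ids_by_direction={"up": list(up_ids), "down": list(down_ids)},
        correlated_pair=pair,
    )
    return matrices, truth


# ---------------------------------------------------------------------------
# Kinase plates


def default_kinase_map(
    n_kinases: int = 8, peptides_per_kinase: int = 4
) -> Dict[str, List[str]]:
    """Disjoint kinase→peptide mapping K1..Kn, 4 sensors each by default."""
    return {
        f"K{k + 1}": [f"K{k + 1}_pep{j + 1}" for j in range(peptides_per_kinase)]
        for k in range(n_kinases)
    }


def build_plate_layout(
    kinase_map: Mapping[str, Sequence[str]],
    samples: Sequence[str],
    standards: Sequence[float] = (0.0, 62.5, 125.0, 250.0),
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Well table skeleton: experimental wells for every sample×peptide×
    replicate plus ATP standards and the three control classes."""
    if len(set(standards)) < 2:
        raise ValueError("need >= 2 distinct ATP standard concentrations")
    peptides = [p for peps in kinase_map.values() for p in peps]
    rows = []

    def add(well_class, peptide="", sample="", replicate=1, conc=np.nan):
        idx = len(rows)
        rows.append(
            {
                "well": f"W{idx + 1:04d}",
                "row": "ABCDEFGHIJKLMNOP"[(idx // 24) % 16],
                "col": idx % 24 + 1,
                "class": well_class,
                "peptide": peptide,
                "sample": sample,
                "replicate": replicate,
                "standard_conc": conc,
                "luminescence": np.nan,
            }
        )

    for conc in standards:
        add("ATP_standard", conc=conc)
    add("no_ATP")
    add("no_sample")
    for sample in samples:
        for rep in range(1, n_replicates + 1):
            add("no_peptide", sample=sample, replicate=rep)
        for peptide in peptides:
            for rep in range(1, n_replicates + 1):
                add("experimental", peptide=peptide, sample=sample, replicate=rep)
    return pd.DataFrame(rows)


def gen_kinase_plate(
    config: SimConfig,
    layout: pd.DataFrame,
    kinase_map: Mapping[str, Sequence[str]],
    treated_samples: Sequence[str] = (),
    atp_start: float = 250.0,
) -> Tuple[PlateAssay, GroundTruth]:
    """Fill a plate layout with luminescence encoding planted kinase effects.

    Luminescence is linear in remaining ATP (slope 4 RLU/nM, offset 100
    RLU) plus multiplicative Gaussian noise of ``plate_noise_cv``. Each
    peptide has a fixed baseline consumption (20–80 nM) and each sample a
    small autonomous background (5–15 nM). In treated samples the peptides
    of each kinase named in ``plate_effect`` consume ``effect × baseline``.
    """
    standards = layout[layout["class"] == "ATP_standard"]["standard_conc"]
    if standards.nunique() < 2:
        raise ValueError("layout needs >= 2 distinct ATP standard concentrations")
    slope, intercept = 4.0, 100.0
    rng_pep, rng_noise = config._rngs(2, stream=2)

    peptides = sorted({p for peps in kinase_map.values() for p in peps})
    base_consumption = dict(
        zip(peptides, rng_pep.uniform(20.0, 80.0, size=len(peptides)))
    )
    kinase_of = {p: k for k, peps in kinase_map.items() for p in peps}
    samples = sorted(set(layout.loc[layout["sample"] != "", "sample"]))
    background = dict(zip(samples, rng_pep.uniform(5.0, 15.0, size=len(samples))))
    treated = set(treated_samples)

    remaining = np.empty(len(layout))
    for idx, row in enumerate(layout.to_dict("records")):
        cls = row["class"]
        if cls == "ATP_standard":
            remaining[idx] = row["standard_conc"]
        elif cls == "no_ATP":
            remaining[idx] = 0.0
        elif cls == "no_sample":
            remaining[idx] = atp_start
        elif cls == "no_peptide":
            remaining[idx] = atp_start - background[row["sample"]]
        else:  # experimental
            c = base_consumption[row["peptide"]]
            if row["sample"] in treated:
                kin = kinase_of.get(row["peptide"])
                if kin in config.plate_effect:
                    c *= config.plate_effect[kin]
            remaining[idx] = atp_start - background[row["sample"]] - c
    if (remaining < 0).any():
        raise ValueError("configured consumption exceeds starting ATP")

    rlu = intercept + slope * remaining
    if config.plate_noise_cv > 0:
        rlu = rlu * (1.0 + config.plate_noise_cv * rng_noise.standard_normal(len(rlu)))
        rlu = np.clip(rlu, 0.0, None)
    wells = layout.copy()
    wells["luminescence"] = rlu
    truth = GroundTruth(kinase_effects=dict(config.plate_effect))
    return PlateAssay(wells=wells, atp_start=atp_start), truth


# ---------------------------------------------------------------------------
# Drug-combination viability


def gen_viability_grid(
    config: SimConfig,
    doses_a: Sequence[float] = (1.0, 2.0, 4.0, 8.0),
    doses_b: Sequence[float] = (1.0, 2.0, 4.0, 8.0),
) -> ViabilityGrid:
    """Dose grid where combined survival deviates from Bliss independence
    by exactly 2^(bliss_deviation), plus multiplicative noise.

    Single agents follow exponential kill curves scaled so the top dose
    leaves ~17% survival. The grid includes the single-agent margins at
    dose 0 and E(0, 0) = 1.
    """
    if not len(doses_a) or not len(doses_b):
        raise ValueError("dose lists must be non-empty")
    rng, = config._rngs(1, stream=3)
    k_a = -np.log(0.168) / max(doses_a)
    k_b = -np.log(0.168) / max(doses_b)
    e_a = {0.0: 1.0, **{float(d): float(np.exp(-k_a * d)) for d in doses_a}}
    e_b = {0.0: 1.0, **{float(d): float(np.exp(-k_b * d)) for d in doses_b}}
    all_a = [0.0] + [float(d) for d in doses_a]
    all_b = [0.0] + [float(d) for d in doses_b]
    grid = np.empty((len(all_a), len(all_b)))
    for i, da in enumerate(all_a):
        for j, db in enumerate(all_b):
            e = e_a[da] * e_b[db]
            if da > 0 and db > 0:
                e *= 2.0**config.bliss_deviation
            if (da, db) != (0.0, 0.0) and config.viability_noise_cv > 0:
                e *= 1.0 + config.viability_noise_cv * rng.standard_normal()
            grid[i, j] = min(max(e, 1e-9), 1.0)
    effect = pd.DataFrame(grid, index=pd.Index(all_a, name="dose_a"),
                          columns=pd.Index(all_b, name="dose_b"))
    return ViabilityGrid(effect=effect)


# ---------------------------------------------------------------------------
# qPCR Ct tables


def gen_ct_table(
    config: SimConfig, design: Mapping[str, object]
) -> Tuple[CtTable, Optional[pd.DataFrame]]:
    """Ct values realizing specified fold changes and, optionally,
    nuclear/cytoplasmic ratios.

    ``design`` keys:
      ``targets``: {gene: true fold change, treated vs control},
      ``housekeeping``: housekeeping gene id (Ct 20 in every sample),
      ``treated_group`` / ``control_group``: group labels,
      ``n_replicates``: samples per group (default 3),
      ``ct_noise_sd``: Gaussian Ct noise in cycles (default 0),
      ``nc_ratios``: optional {gene: true nuclear/cytoplasmic ratio}.

    Fold changes are encoded exactly as ΔΔCt = −log2(fold) on the target
    gene with the housekeeping gene flat; N/C ratios are encoded as
    Ct_nuclear = Ct_cytoplasmic − log2(ratio).
    """
    targets: Mapping[str, float] = design["targets"]
    for gene, fold in targets.items():
        if fold <= 0:
            raise ValueError(f"fold change for {gene!r} must be positive")
    housekeeping = design.get("housekeeping", "GAPDH")
    treated = design.get("treated_group", "treated")
    control = design.get("control_group", "control")
    n_rep = int(design.get("n_replicates", 3))
    noise_sd = float(design.get("ct_noise_sd", 0.0))
    rng, = config._rngs(1, stream=4)

    hk_ct, target_ct0 = 20.0, 25.0
    rows = []
    for group in (control, treated):
        for rep in range(1, n_rep + 1):
            sample = f"{group}_{rep}"
            rows.append({"sample": sample, "group": group, "gene": housekeeping,
                         "ct": hk_ct + noise_sd * rng.standard_normal()})
            for gene, fold in targets.items():
                ct = target_ct0 - (np.log2(fold) if group == treated else 0.0)
                rows.append({"sample": sample, "group": group, "gene": gene,
                             "ct": ct + noise_sd * rng.standard_normal()})
    ct_table = CtTable(rows=pd.DataFrame(rows), housekeeping=housekeeping)

    fractions = None
    if "nc_ratios" in design:
        ct_cyto = 26.0
        frac_rows = {
            gene: {
                "ct_nuclear": ct_cyto - float(np.log2(ratio))
                + noise_sd * rng.standard_normal(),
                "ct_cytoplasmic": ct_cyto + noise_sd * rng.standard_normal(),
            }
            for gene, ratio in design["nc_ratios"].items()
        }
        fractions = pd.DataFrame.from_dict(frac_rows, orient="index")
        fractions.index.name = "gene"
    return ct_table, fractions
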