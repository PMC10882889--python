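"""Peptide-sensor kinase-activity mapping from 384-well luminescence plates.

The assay measures kinase activity indirectly: each experimental well holds
one 11-mer peptide sensor, a cell-lysate sample and 250 nM ATP; active
kinases consume ATP while phosphorylating the peptide, and a luciferase
readout reports the ATP that remains, so luminescence is inversely related
to activity. Side-by-side ATP standards calibrate RLU→nM; a matched
no-peptide well per sample removes sample-autonomous ATP consumption;
no-ATP wells give the luminescence offset and no-sample wells verify that
ATP survives without enzyme.

Kinase activity is derived as the mean of the activities of the peptides
mapped to that kinase (kinases with fewer than three measured peptides are
dropped). Profiles are clustered with uncentered correlation and average
linkage — the classic Cluster 3.0 convention — with deterministic
index-order tie-breaking, and treatment signatures are compared by Pearson
correlation of their log2 ratios to a matched control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlateAssay",
    "Calibration",
    "ActivityProfile",
    "KinaseSignature",
    "read_plate_csv",
    "read_kinase_map",
    "calibrate_atp",
    "peptide_activity",
    "kinase_signature",
    "uncentered_correlation_distance",
    "cluster_profiles",
    "linkage_to_newick",
    "compare_signatures",
]

WELL_CLASSES = ("experimental", "no_ATP", "no_peptide", "no_sample", "ATP_standard")

_LAYOUT_COLUMNS = [
    "well", "row", "col", "class", "peptide", "sample", "replicate",
    "standard_conc", "luminescence",
]


@dataclass
class PlateAssay:
    """Well table (layout + luminescence) for one plate run.

    ``wells`` columns: well, row, col, class, peptide, sample, replicate,
    standard_conc, luminescence. Unused fields hold empty strings / NaN.
    """

    wells: pd.DataFrame
    atp_start: float = 250.0  # nM

    def __post_init__(self) -> None:
        missing = set(_LAYOUT_COLUMNS) - set(self.wells.columns)
        if missing:
            raise ValueError(f"plate table missing columns: {sorted(missing)}")
        bad = set(self.wells["class"]) - set(WELL_CLASSES)
        if bad:
            raise ValueError(f"unknown well classes: {sorted(bad)}")
        if (self.wells["luminescence"] < 0).any():
            raise ValueError("luminescence must be non-negative")

    def of_class(self, well_class: str) -> pd.DataFrame:
        return self.wells[self.wells["class"] == well_class]


def read_plate_csv(path, atp_start: float = 250.0) -> PlateAssay:
    wells = pd.read_csv(path, dtype={"peptide": str, "sample": str, "well": str})
    return PlateAssay(wells=wells, atp_start=atp_start)


def write_plate_csv(assay: PlateAssay, path) -> None:
    assay.wells.to_csv(path, index=False)


def read_kinase_map(path) -> Dict[str, Set[str]]:
    """TSV with columns (kinase, peptide) -> kinase -> set of peptide ids."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    mapping: Dict[str, Set[str]] = {}
    for kinase, peptide in zip(table["kinase"], table["peptide"]):
        mapping.setdefault(kinase, set()).add(peptide)
    return mapping


# ---------------------------------------------------------------------------
# Calibration and activity derivation


@dataclass(frozen=True)
class Calibration:
    slope: float       # RLU per nM ATP
    intercept: float   # RLU at zero ATP (luminescence offset)
    r_squared: float

    def atp_from_rlu(self, rlu: float) -> float:
        return (rlu - self.intercept) / self.slope


def calibrate_atp(assay: PlateAssay) -> Calibration:
    """Least-squares line RLU = slope·[ATP] + intercept from standard wells."""
    standards = assay.of_class("ATP_standard")
    conc = standards["standard_conc"].to_numpy(dtype=float)
    rlu = standards["luminescence"].to_numpy(dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("need >= 2 distinct ATP standard concentrations")
    fit = stats.linregress(conc, rlu)
    if fit.slope <= 0:
        raise ValueError(f"non-positive calibration slope {fit.slope:.4g}: failed plate")
    return Calibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


@dataclass
class ActivityProfile:
    sample_id: str
    peptide_activities: Dict[str, float]  # nM ATP consumed, background-corrected


def peptide_activity(
    assay: PlateAssay, calibration: Calibration
) -> List[ActivityProfile]:
    """Background-corrected per-peptide ATP consumption per sample.

    Replicate wells of the same (sample, peptide) are averaged first. The
    consumption of the sample's matched no-peptide well (its autonomous ATP
    use) is subtracted from every peptide well of that sample.
    """
    def consumed(rlu: float) -> float:
        return assay.atp_start - calibration.atp_from_rlu(rlu)

    background: Dict[str, float] = {}
    for sample, group in assay.of_class("no_peptide").groupby("sample"):
        background[sample] = consumed(group["luminescence"].mean())

    profiles: List[ActivityProfile] = []
    for sample, group in assay.of_class("experimental").groupby("sample", sort=True):
        if sample not in background:
            raise ValueError(f"no matched no-peptide control for sample {sample!r}")
        activities = {
            peptide: consumed(sub["luminescence"].mean()) - background[sample]
            for peptide, sub in group.groupby("peptide", sort=True)
        }
        profiles.append(ActivityProfile(sample_id=sample, peptide_activities=activities))
    return profiles


@dataclass
class KinaseSignature:
    sample_id: str
    kinase_activities: Dict[str, float]
    n_peptides_used: Dict[str, int]


def kinase_signature(
    profiles: Sequence[ActivityProfile],
    kinase_map: Mapping[str, Set[str]],
    min_peptides: int = 3,
    aggregator: str = "mean",
) -> List[KinaseSignature]:
    """Aggregate peptide activities into per-kinase activities.

    A kinase is reported only when at least ``min_peptides`` of its mapped
    peptides were measured; its activity is the mean (or median) of those
    peptide activities.
    """
    if not kinase_map:
        raise ValueError("empty kinase -> peptide mapping")
    agg: Callable[[List[float]], float] = {
        "mean": lambda v: float(np.mean(v)),
        "median": lambda v: float(np.median(v)),
    }[aggregator]
    signatures = []
    for profile in profiles:
        activities: Dict[str, float] = {}
        counts: Dict[str, int] = {}
        for kinase, peptides in kinase_map.items():
            measured = [
                profile.peptide_activities[p]
                for p in sorted(peptides)
                if p in profile.peptide_activities
            ]
            if len(measured) >= min_peptides:
                activities[kinase] = agg(measured)
                counts[kinase] = len(measured)
        signatures.append(
            KinaseSignature(
                sample_id=profile.sample_id,
                kinase_activities=activities,
                n_peptides_used=counts,
            )
        )
    return signatures


# ---------------------------------------------------------------------------
# Clustering


def uncentered_correlation_distance(matrix: np.ndarray) -> np.ndarray:
    """Pairwise d(x, y) = 1 − Σxᵢyᵢ / (‖x‖·‖y‖) between the rows.

    Scale-invariant for positive scalings but, unlike Pearson, not shift
    invariant. Rows that are exactly zero have no defined angle; they get
    the maximal distance 1 to every other row (0 to themselves).
    """
    x = np.asarray(matrix, dtype=float)
    norms = np.linalg.norm(x, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero vector(s); assigned distance 1")
    safe = np.where(zero, 1.0, norms)
    unit = x / safe[:, None]
    sim = unit @ unit.T
    d = 1.0 - sim
    d[zero, :] = 1.0
    d[:, zero] = 1.0
    np.fill_diagonal(d, 0.0)
    # numerical noise can leave tiny negatives
    return np.clip(d, 0.0, None)


def upgma(dist: np.ndarray) -> np.ndarray:
    """Average-linkage agglomeration of a square distance matrix.

    Returns a scipy-style linkage matrix (n−1)×4. Ties on the minimum
    distance are broken by the smallest pair of cluster ids (leaves are
    0..n−1, internal nodes n, n+1, … in creation order), which makes the
    merge sequence deterministic.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need >= 2 items to cluster")
    d: Dict[Tuple[int, int], float] = {
        (i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = []
    next_id = n
    while len(active) > 1:
        (i, j), height = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        for k in active - {i, j}:
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            d[(min(k, next_id), max(k, next_id))] = (
                size[i] * dik + size[j] * djk
            ) / (size[i] + size[j])
        del d[(i, j)]
        merges.append([i, j, height, size[i] + size[j]])
        size[next_id] = size[i] + size[j]
        active -= {i, j}
        active.add(next_id)
        next_id += 1
    return np.array(merges, dtype=float)


def _leaf_order(linkage: np.ndarray, n: int) -> List[int]:
    children = {n + k: (int(row[0]), int(row[1])) for k, row in enumerate(linkage)}

    def walk(node: int) -> List[int]:
        if node < n:
            return [node]
        left, right = children[node]
        return walk(left) + walk(right)

    return walk(n + len(linkage) - 1)


def cluster_profiles(
    matrix: pd.DataFrame, axis: str = "rows"
) -> Tuple[np.ndarray, List[str]]:
    """Cluster the rows (or columns) of a feature×sample table.

    Returns (linkage matrix, labels in dendrogram leaf order). Distance is
    uncentered correlation; linkage is UPGMA with deterministic tie-breaks.
    """
    if axis == "columns":
        matrix = matrix.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    labels = [str(x) for x in matrix.index]
    linkage = upgma(uncentered_correlation_distance(matrix.to_numpy(dtype=float)))
    order = _leaf_order(linkage, len(labels))
    return linkage, [labels[i] for i in order]


def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Render a linkage matrix as a Newick string with ultrametric branch
    lengths (node height = merge distance / 2)."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes: Dict[int, str] = {i: str(labels[i]) for i in range(n)}
    for k, (a, b, height, _) in enumerate(linkage):
        a, b = int(a), int(b)
        h = height / 2.0
        la = h - heights[a]
        lb = h - heights[b]
        node = n + k
        nodes[node] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[node] = h
    return nodes[n + len(linkage) - 1] + ";"


# ---------------------------------------------------------------------------
# Signature comparison


def compare_signatures(
    sig_a: KinaseSignature,
    sig_b: KinaseSignature,
    control: KinaseSignature,
) -> float:
    """Pearson r between two treatment signatures after control normalization.

    Each signature is expressed as log2(activity / control activity) over
    the kinases shared by all three; kinases with a non-positive activity
    in any of the three are dropped (log ratio undefined) with a warning.
    """
    shared = (
        set(sig_a.kinase_activities)
        & set(sig_b.kinase_activities)
        & set(control.kinase_activities)
    )
    if not shared:
        raise ValueError("no shared kinases between signatures")
    usable = sorted(
        k
        for k in shared
        if sig_a.kinase_activities[k] > 0
        and sig_b.kinase_activities[k] > 0
        and control.kinase_activities[k] > 0
    )
    if len(usable) < len(shared):
        warnings.warn(
            f"dropped {len(shared) - len(usable)} kinase(s) with non-positive activity"
        )
    if len(usable) < 3:
        raise ValueError("fewer than 3 usable kinases for correlation")
    ra = np.log2(
        [sig_a.kinase_activities[k] / control.kinase_activities[k] for k in usable]
    )
    rb = np.log2(
        [sig_b.kinase_activities[k] / control.kinase_activities[k] for k in usable]
    )
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        raise ValueError("constant signature after normalization")
    return float(stats.pearsonr(ra, rb)[0])
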