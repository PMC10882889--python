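"""Closed-form analytics for drug combinations, qPCR and xenograft readouts.

* Bliss-style combination index: CI = log2(E_ab / (E_a·E_b)) with E the
  control-normalized surviving fraction; CI < 0 means the combination kills
  more than the independence expectation (synergy), CI > 0 antagonism.
* Comparative-Ct relative expression (ΔΔCt, amplification efficiency 2).
* Nuclear/cytoplasmic enrichment normalized to a nuclear reference RNA.
* Growth normalization, the caliper tumor-volume formula, and the
  two-sample Student's t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ViabilityGrid",
    "CIResult",
    "CtTable",
    "combination_index",
    "relative_expression",
    "nc_ratio",
    "growth_normalize",
    "tumor_volume",
    "two_sample_test",
]


@dataclass
class ViabilityGrid:
    """Dose-pair fractional effects relative to untreated control.

    ``effect``: DataFrame indexed by dose of drug A (rows) with doses of
    drug B as columns, in (0, 1]. Row/column at dose 0 hold the
    single-agent effects (E at (0, 0) is 1 by construction).
    """

    effect: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.effect.to_numpy(dtype=float)
        if (vals <= 0).any() or (vals > 1).any():
            raise ValueError("effects must be surviving fractions in (0, 1]")

    @property
    def doses_a(self) -> List[float]:
        return [float(d) for d in self.effect.index]

    @property
    def doses_b(self) -> List[float]:
        return [float(d) for d in self.effect.columns]

    def single_agent_a(self, dose: float) -> float:
        return float(self.effect.loc[dose, 0.0])

    def single_agent_b(self, dose: float) -> float:
        return float(self.effect.loc[0.0, dose])


@dataclass
class CIResult:
    ci_matrix: pd.DataFrame  # log2 units, NaN on single-agent margins
    mean_ci: float


def combination_index(grid: ViabilityGrid, strict_sign: bool = False) -> CIResult:
    """Combination index per dose pair, averaged over the grid.

    CI(a, b) = log2(E_ab / (E_a · E_b)) for every dose pair with both doses
    positive; E_a, E_b are the single-agent surviving fractions at the same
    doses. ``strict_sign=True`` instead evaluates log2(E_ab / (−E_a·E_b))
    with E recoded as negative growth change (E − 1), for comparison with
    the literal printed formula; it is not the default because only the
    ratio-of-survivals form yields CI < 0 ⇔ synergy for fractional
    survivals.
    """
    if 0.0 not in grid.effect.index or 0.0 not in grid.effect.columns:
        raise ValueError("grid needs single-agent margins at dose 0")
    rows = []
    for da in grid.doses_a:
        row = []
        for db in grid.doses_b:
            if da == 0.0 or db == 0.0:
                row.append(np.nan)
                continue
            e_ab = float(grid.effect.loc[da, db])
            e_a = grid.single_agent_a(da)
            e_b = grid.single_agent_b(db)
            if strict_sign:
                arg = (e_ab - 1.0) / (-(e_a - 1.0) * (e_b - 1.0))
                row.append(np.log2(arg) if arg > 0 else np.nan)
            else:
                row.append(float(np.log2(e_ab / (e_a * e_b))))
        rows.append(row)
    ci = pd.DataFrame(rows, index=grid.effect.index, columns=grid.effect.columns)
    return CIResult(ci_matrix=ci, mean_ci=float(np.nanmean(ci.to_numpy())))


@dataclass
class CtTable:
    """Long-format qPCR Ct values: (sample, group, gene, ct)."""

    rows: pd.DataFrame  # columns: sample, group, gene, ct
    housekeeping: str

    def __post_init__(self) -> None:
        needed = {"sample", "group", "gene", "ct"}
        if not needed <= set(self.rows.columns):
            raise ValueError(f"Ct table needs columns {sorted(needed)}")
        if (self.rows["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")


def _delta_ct(ct: CtTable, target: str, group: str) -> np.ndarray:
    sub = ct.rows[ct.rows["group"] == group]
    tgt = sub[sub["gene"] == target].set_index("sample")["ct"]
    hk = sub[sub["gene"] == ct.housekeeping].set_index("sample")["ct"]
    if hk.empty:
        raise ValueError(f"housekeeping gene {ct.housekeeping!r} missing in group {group!r}")
    if tgt.empty:
        raise ValueError(f"target {target!r} missing in group {group!r}")
    common = tgt.index.intersection(hk.index)
    if common.empty:
        raise ValueError("no samples with both target and housekeeping Ct")
    return (tgt.loc[common] - hk.loc[common]).to_numpy(dtype=float)


def relative_expression(
    ct: CtTable, target: str, treated_group: str, control_group: str
) -> float:
    """Comparative-Ct fold change of ``target`` in treated vs control.

    ΔCt = Ct_target − Ct_housekeeping per sample; ΔΔCt = mean ΔCt(treated)
    − mean ΔCt(control); fold = 2^(−ΔΔCt), assuming a doubling per cycle.
    """
    ddct = _delta_ct(ct, target, treated_group).mean() - _delta_ct(
        ct, target, control_group
    ).mean()
    return float(2.0 ** (-ddct))


def nc_ratio(fractions: pd.DataFrame, gene: str, control_gene: str) -> float:
    """Nuclear-to-cytoplasmic enrichment normalized to a nuclear control RNA.

    ``fractions``: DataFrame indexed by gene with columns ``ct_nuclear``
    and ``ct_cytoplasmic``. Raw N/C per gene = 2^(Ct_cyto − Ct_nuc) — one
    cycle earlier in the nuclear fraction means twice the nuclear RNA. The
    returned value is raw(gene) / raw(control_gene); no housekeeping gene
    is used because the two fractions are not comparable through one.
    """
    for g in (gene, control_gene):
        if g not in fractions.index:
            raise KeyError(f"gene {g!r} absent from fraction table")

    def raw(g: str) -> float:
        row = fractions.loc[g]
        return float(2.0 ** (row["ct_cytoplasmic"] - row["ct_nuclear"]))

    return raw(gene) / raw(control_gene)


def growth_normalize(
    lum: Mapping[str, float], control_samples: Sequence[str]
) -> Dict[str, float]:
    """Fractional cell growth relative to the mean of control wells."""
    if not control_samples:
        raise ValueError("empty control set")
    control_mean = float(np.mean([lum[s] for s in control_samples]))
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return {s: float(v) / control_mean for s, v in lum.items()}


def tumor_volume(length: float, width: float, swap_axes: bool = True) -> float:
    """Caliper tumor volume V = 0.5 · L · W² (mm³).

    Convention: length is the longer axis. If width > length the axes are
    swapped (with a warning) unless ``swap_axes=False``.
    """
    if length <= 0 or width <= 0:
        raise ValueError("dimensions must be positive")
    if width > length:
        warnings.warn(f"width {width} > length {length}; axis convention violated")
        if swap_axes:
            length, width = width, length
    return 0.5 * length * width**2


def two_sample_test(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True
) -> Tuple[float, float]:
    """Two-sided two-sample t-test; classical Student form by default.

    Returns (t, p). With zero variance in both groups and equal means the
    statistic is undefined and (nan, nan) is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 observations")
    if x.std() == 0 and y.std() == 0:
        if x.mean() == y.mean():
            return float("nan"), float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)
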