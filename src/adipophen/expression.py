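"""Relative expression quantification: qPCR fold changes and blot densitometry.

qPCR fold changes follow the comparative-Ct scheme: per sample,
dCt = Ct(target) - Ct(reference gene); the control group's mean dCt is the
baseline, and fold = 2 ** -(dCt - baseline).  With the 18s reference and
wild-type controls this expresses each sample relative to the control
group, whose fold changes then average (geometrically) to exactly 1.

Densitometry divides each lane's protein band intensity by its loading
control (β-actin), giving normalised integrated density values (IDV).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidTableError

CONTROL = "control"
TEST = "test"


@dataclass
class CtTable:
    """Long-format qPCR table: sample_id, group (control/test), gene, ct."""

    records: pd.DataFrame
    reference_gene: str = "18s"

    def __post_init__(self) -> None:
        req = {"sample_id", "group", "gene", "ct"}
        missing = req - set(self.records.columns)
        if missing:
            raise InvalidTableError(f"Ct table missing columns: {sorted(missing)}")
        ct = self.records["ct"]
        if not np.all(np.isfinite(ct)) or (ct <= 0).any():
            raise InvalidTableError("Ct values must be finite and positive")


@dataclass
class DensitometryTable:
    """Long-format blot table: lane_id, group, protein, intensity."""

    records: pd.DataFrame
    loading_control: str = "beta-actin"

    def __post_init__(self) -> None:
        req = {"lane_id", "group", "protein", "intensity"}
        missing = req - set(self.records.columns)
        if missing:
            raise InvalidTableError(f"densitometry table missing columns: {sorted(missing)}")
        if (self.records["intensity"] < 0).any():
            raise InvalidTableError("intensities must be nonnegative")


@dataclass(frozen=True)
class FoldChangeResult:
    gene: str
    reference_gene: str
    per_sample: pd.DataFrame  # sample_id, group, delta_ct, fold_change
    group_means: pd.Series
    baseline_delta_ct: float


def fold_change(table: CtTable, gene: str) -> FoldChangeResult:
    """Comparative-Ct fold change of ``gene`` against the reference gene,
    relative to the control-group baseline.

    Samples lacking a reference-gene measurement are dropped with a warning;
    a table with no control samples for the gene is an error.
    """
    df = table.records
    tgt = df[df["gene"] == gene].set_index("sample_id")
    ref = df[df["gene"] == table.reference_gene].set_index("sample_id")
    if tgt.empty:
        raise InvalidTableError(f"gene {gene!r} absent from the table")
    missing_ref = tgt.index.difference(ref.index)
    if len(missing_ref):
        warnings.warn(
            f"dropping samples without reference gene: {sorted(missing_ref)}",
            stacklevel=2,
        )
        tgt = tgt.drop(index=missing_ref)
    delta_ct = tgt["ct"] - ref.loc[tgt.index, "ct"]
    groups = tgt["group"]
    control_dct = delta_ct[groups == CONTROL]
    if control_dct.empty:
        raise InvalidTableError(f"no control samples measure gene {gene!r}")
    baseline = float(control_dct.mean())
    fold = 2.0 ** -(delta_ct - baseline)
    per_sample = pd.DataFrame(
        {
            "sample_id": tgt.index,
            "group": groups.to_numpy(),
            "delta_ct": delta_ct.to_numpy(),
            "fold_change": fold.to_numpy(),
        }
    ).reset_index(drop=True)
    group_means = per_sample.groupby("group")["fold_change"].mean()
    return FoldChangeResult(
        gene=gene,
        reference_gene=table.reference_gene,
        per_sample=per_sample,
        group_means=group_means,
        baseline_delta_ct=baseline,
    )


def fold_change_interval(
    table: CtTable, gene: str, confidence: float = 0.95
) -> tuple[float, float, float]:
    """Test-group fold change with a Welch-t confidence interval.

    The interval is built on the test-vs-control difference of mean dCt
    (where the arithmetic is normal-ish) and exponentiated, giving an
    asymmetric interval on the fold scale: ``(point, low, high)``.
    """
    from scipy import stats

    res = fold_change(table, gene)
    dct = res.per_sample.set_index("sample_id")["delta_ct"]
    grp = res.per_sample.set_index("sample_id")["group"]
    c = dct[grp == CONTROL].to_numpy()
    t = dct[grp == TEST].to_numpy()
    if len(c) < 2 or len(t) < 2:
        raise InvalidTableError("need >= 2 samples per group for an interval")
    ddct = t.mean() - c.mean()
    se = np.sqrt(t.var(ddof=1) / len(t) + c.var(ddof=1) / len(c))
    if se == 0:
        point = 2.0**-ddct
        return point, point, point
    df = se**4 / (
        (t.var(ddof=1) / len(t)) ** 2 / (len(t) - 1)
        + (c.var(ddof=1) / len(c)) ** 2 / (len(c) - 1)
    )
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df)
    point = 2.0**-ddct
    return point, 2.0 ** -(ddct + tcrit * se), 2.0 ** -(ddct - tcrit * se)


@dataclass(frozen=True)
class DensitometryResult:
    protein: str
    loading_control: str
    per_lane: pd.DataFrame  # lane_id, group, idv
    group_means: pd.Series


def normalize_densitometry(
    table: DensitometryTable,
    protein: str,
    rescale_to_control: bool = False,
) -> DensitometryResult:
    """Per-lane protein intensity divided by the lane's loading control.

    Lanes with a zero loading control are dropped with a warning.  With
    ``rescale_to_control`` the IDVs are further divided by the control-group
    mean so controls average to 1.
    """
    df = table.records
    prot = df[df["protein"] == protein].set_index("lane_id")
    ctrl = df[df["protein"] == table.loading_control].set_index("lane_id")
    if prot.empty:
        raise InvalidTableError(f"protein {protein!r} absent from the table")
    common = prot.index.intersection(ctrl.index)
    if len(common) < len(prot):
        warnings.warn("lanes without a loading control were dropped", stacklevel=2)
    prot = prot.loc[common]
    denom = ctrl.loc[common, "intensity"]
    zero = denom == 0
    if zero.any():
        warnings.warn(
            f"dropping lanes with zero loading control: {sorted(common[zero])}",
            stacklevel=2,
        )
        prot, denom = prot.loc[~zero.to_numpy()], denom[~zero]
    if prot.empty:
        raise InvalidTableError("no usable lanes")
    idv = prot["intensity"] / denom
    if rescale_to_control:
        ctrl_mean = idv[prot["group"] == CONTROL].mean()
        if not np.isfinite(ctrl_mean) or ctrl_mean == 0:
            raise InvalidTableError("cannot rescale: control-group mean IDV is 0 or absent")
        idv = idv / ctrl_mean
    per_lane = pd.DataFrame(
        {
            "lane_id": prot.index,
            "group": prot["group"].to_numpy(),
            "idv": idv.to_numpy(),
        }
    ).reset_index(drop=True)
    return DensitometryResult(
        protein=protein,
        loading_control=table.loading_control,
        per_lane=per_lane,
        group_means=per_lane.groupby("group")["idv"].mean(),
    )
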