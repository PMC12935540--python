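"""Quality control of long-format yield tables.

The screen mirrors standard practice for long-term rotation experiments:

* yields are converted to dry weight from their reported water content;
* missing values, zeros without an agronomic annotation ("unexplained
  zeros") and values outside ``[Q1 - 2*IQR, Q3 + 2*IQR]`` per site x crop
  are flagged;
* flagged values are gap filled by the mean of donor records sharing crop,
  site, calendar year, rotation and treatment (differing only in replicate);
* when no donor exists, the whole site x rotation x year x treatment
  combination is excluded from downstream aggregation and reported.

Explained zeros (fallow years, annotated frost damage) are kept as genuine
zero yields, and low but non-zero yields inside the bounds are retained —
they plausibly reflect poor growing conditions, not reporting errors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

FLAG_OK = "ok"
FLAG_MISSING = "missing"
FLAG_UNEXPLAINED_ZERO = "unexplained_zero"
FLAG_EXPLAINED_ZERO = "explained_zero"
FLAG_IMPLAUSIBLE = "implausible"
FLAG_GAP_FILLED = "gap_filled"
FLAG_EXCLUDED = "excluded"

#: Minimum number of usable values for a site x crop outlier screen.
MIN_GROUP_SIZE = 4

_KEY_COLS = ("site", "calendar_year", "rotation_id", "group", "crop")


@dataclass
class QCReport:
    """Summary of a QC pass: flag counts, exclusions and anomaly fractions."""

    n_records: int = 0
    flag_counts: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=list)
    missing_fraction: float = 0.0
    zero_fraction: float = 0.0
    skipped_outlier_groups: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "flag_counts": self.flag_counts,
            "exclusions": self.exclusions,
            "missing_fraction": self.missing_fraction,
            "zero_fraction": self.zero_fraction,
            "skipped_outlier_groups": self.skipped_outlier_groups,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def to_dry_weight(yield_raw, water_content):
    """Convert fresh yield to dry weight: ``yield_raw * (1 - water_content)``."""
    wc = np.asarray(water_content, dtype=float)
    if np.any(wc >= 1.0) or np.any(wc < 0.0):
        raise ValueError("water_content must be in [0, 1)")
    out = np.asarray(yield_raw, dtype=float) * (1.0 - wc)
    return out if out.ndim else float(out)


def _ensure_dry(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    if "yield_dry" not in table.columns:
        if "yield_raw" not in table.columns:
            raise ValueError("table needs a yield_dry or a yield_raw column")
        wc = table.get("water_content", pd.Series(0.0, index=table.index))
        wc = wc.fillna(0.0).to_numpy(dtype=float)
        if np.any(wc >= 1.0) or np.any(wc < 0.0):
            raise ValueError("water_content must be in [0, 1)")
        table["yield_dry"] = table["yield_raw"].to_numpy(dtype=float) * (1.0 - wc)
    return table


def flag_records(table: pd.DataFrame) -> pd.DataFrame:
    """Assign base QC flags (missing / explained zero / unexplained zero).

    A zero yield counts as explained when a non-empty ``note`` annotation is
    present (e.g. "fallow", "frost"); all fallow crop rows are explained
    structural zeros.
    """
    table = _ensure_dry(table)
    y = table["yield_dry"]
    note = table.get("note", pd.Series("", index=table.index)).fillna("")
    is_fallow = table["crop"].eq("fallow") if "crop" in table.columns else False
    flags = np.where(
        y.isna(),
        FLAG_MISSING,
        np.where(
            y.eq(0.0),
            np.where(note.ne("") | is_fallow, FLAG_EXPLAINED_ZERO, FLAG_UNEXPLAINED_ZERO),
            FLAG_OK,
        ),
    )
    table["qc_flag"] = flags
    return table


def flag_outliers(
    table: pd.DataFrame, k: float = 2.0, quantile_method: str = "linear"
) -> pd.DataFrame:
    """Flag yields outside ``[Q1 - k*IQR, Q3 + k*IQR]`` per site x crop.

    Quartiles pool all years within each site x crop combination and are
    computed over currently-ok records (zeros are handled by their own
    flags and do not enter the bounds).  Bounds are closed intervals:
    values exactly on a bound are kept.  Groups with fewer than
    :data:`MIN_GROUP_SIZE` usable values are skipped with a warning.

    The default quartile convention is linear interpolation (numpy's
    ``method="linear"``, R type 7); it is configurable because flags can
    differ at small group sizes.
    """
    if "qc_flag" not in table.columns:
        table = flag_records(table)
    else:
        table = table.copy()
    skipped = []
    for (site, crop), sub in table.groupby(["site", "crop"], sort=False):
        ok = sub[sub["qc_flag"] == FLAG_OK]
        vals = ok["yield_dry"].to_numpy(dtype=float)
        if len(vals) < MIN_GROUP_SIZE:
            if crop != "fallow":
                skipped.append((str(site), str(crop)))
                logger.warning(
                    "outlier screen skipped for site=%s crop=%s (%d usable values)",
                    site, crop, len(vals),
                )
            continue
        q1, q3 = np.quantile(vals, [0.25, 0.75], method=quantile_method)
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        out = ok.index[(vals < lo) | (vals > hi)]
        table.loc[out, "qc_flag"] = FLAG_IMPLAUSIBLE
        if len(out):
            logger.info(
                "site=%s crop=%s: %d value(s) outside [%.3g, %.3g] flagged implausible",
                site, crop, len(out), lo, hi,
            )
    table.attrs["skipped_outlier_groups"] = skipped
    return table


def _treatment_col(table: pd.DataFrame) -> pd.Series:
    # Donors must share "other treatments" and differ only in replicate; a
    # table without a treatment column is read as replicates of one treatment.
    if "treatment" in table.columns:
        return table["treatment"].astype(str)
    return pd.Series("", index=table.index)


def gap_fill(
    table: pd.DataFrame,
    keep_unexplained_zeros: bool = False,
    fill_outliers: bool = True,
) -> tuple:
    """Replace flagged yields by donor means; exclude combinations without donors.

    Targets are records flagged missing, unexplained zero (unless
    ``keep_unexplained_zeros``) and implausible (unless ``fill_outliers`` is
    off — flagged outliers are treated as missing by default because the
    plausibility decision cannot be automated).  Donors share site, crop,
    calendar year, rotation and treatment with the target and carry flag
    ``ok``.  A target without donors causes the exclusion of its whole
    site x rotation x year x treatment combination.

    Returns ``(table, QCReport)``.  The operation is idempotent: a second
    pass finds no remaining targets.  Original flags are preserved in a
    ``qc_history`` column.
    """
    if "qc_flag" not in table.columns:
        table = flag_records(table)
    else:
        table = table.copy()
    if "qc_history" not in table.columns:
        table["qc_history"] = table["qc_flag"]

    n = len(table)
    missing_frac = float((table["qc_flag"] == FLAG_MISSING).mean()) if n else 0.0
    zero_frac = float((table["qc_flag"] == FLAG_UNEXPLAINED_ZERO).mean()) if n else 0.0

    target_flags = {FLAG_MISSING}
    if not keep_unexplained_zeros:
        target_flags.add(FLAG_UNEXPLAINED_ZERO)
    if fill_outliers:
        target_flags.add(FLAG_IMPLAUSIBLE)

    treatment = _treatment_col(table)
    donor_keys = ["site", "crop", "calendar_year", "rotation_id"]
    ok_mask = table["qc_flag"] == FLAG_OK
    donor_tab = table[ok_mask]
    donor_means = (
        donor_tab.assign(_trt=treatment[ok_mask])
        .groupby(donor_keys + ["_trt"])["yield_dry"]
        .mean()
    )

    exclusions = []
    targets = table.index[table["qc_flag"].isin(target_flags)]
    for idx in targets:
        row = table.loc[idx]
        key = tuple(row[c] for c in donor_keys) + (treatment.loc[idx],)
        if key in donor_means.index:
            table.loc[idx, "yield_dry"] = float(donor_means.loc[key])
            table.loc[idx, "qc_flag"] = FLAG_GAP_FILLED
        else:
            exclusions.append(
                {
                    "site": str(row["site"]),
                    "rotation_id": str(row["rotation_id"]),
                    "calendar_year": int(row["calendar_year"]),
                    "treatment": str(treatment.loc[idx]),
                }
            )

    # Drop duplicates, then mark every record of an excluded combination.
    uniq = {tuple(sorted(e.items())): e for e in exclusions}
    exclusions = list(uniq.values())
    for e in exclusions:
        m = (
            table["site"].astype(str).eq(e["site"])
            & table["rotation_id"].astype(str).eq(e["rotation_id"])
            & table["calendar_year"].eq(e["calendar_year"])
            & treatment.eq(e["treatment"])
        )
        table.loc[m, "qc_flag"] = FLAG_EXCLUDED
        logger.info("excluded combination with no gap-fill donors: %s", e)

    report = QCReport(
        n_records=n,
        flag_counts={k: int(v) for k, v in table["qc_flag"].value_counts().items()},
        exclusions=exclusions,
        missing_fraction=missing_frac,
        zero_fraction=zero_frac,
        skipped_outlier_groups=[
            list(t) for t in table.attrs.get("skipped_outlier_groups", [])
        ],
    )
    return table, report


class YieldQC(BaseEstimator, TransformerMixin):
    """QC transformer: dry-weight conversion, flagging, outlier screen, gap fill.

    Parameters
    ----------
    k : float
        IQR multiplier of the outlier screen.
    quantile_method : str
        Quartile convention passed to :func:`numpy.quantile`.
    gap_fill : bool
        Whether to gap fill flagged records; off supports the sensitivity run
        in which conclusions are re-checked without filling.
    keep_unexplained_zeros : bool
        Keep zero yields without annotation as genuine zeros (sensitivity run).
    screen_outliers : bool
        Whether to run the IQR screen at all.

    After :meth:`transform`, the last QC report is available as ``report_``.
    """

    def __init__(
        self,
        k: float = 2.0,
        quantile_method: str = "linear",
        gap_fill: bool = True,
        keep_unexplained_zeros: bool = False,
        screen_outliers: bool = True,
    ):
        self.k = k
        self.quantile_method = quantile_method
        self.gap_fill = gap_fill
        self.keep_unexplained_zeros = keep_unexplained_zeros
        self.screen_outliers = screen_outliers

    def fit(self, X: pd.DataFrame, y=None):
        missing = {c for c in _KEY_COLS if c not in X.columns}
        if missing:
            raise ValueError(f"yield table is missing columns: {sorted(missing)}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit(X)
        table = flag_records(X)
        if self.screen_outliers:
            table = flag_outliers(table, k=self.k, quantile_method=self.quantile_method)
        if self.gap_fill:
            table, report = gap_fill(
                table, keep_unexplained_zeros=self.keep_unexplained_zeros
            )
        else:
            table["qc_history"] = table["qc_flag"]
            report = QCReport(
                n_records=len(table),
                flag_counts={
                    k: int(v) for k, v in table["qc_flag"].value_counts().items()
                },
                exclusions=[],
                missing_fraction=float((table["qc_flag"] == FLAG_MISSING).mean()),
                zero_fraction=float(
                    (table["qc_flag"] == FLAG_UNEXPLAINED_ZERO).mean()
                ),
            )
        self.report_ = report
        return table
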