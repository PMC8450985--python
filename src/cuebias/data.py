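"""Study data model, trial-table I/O, RT filtering and behavioral summaries.

A study is trial-level behavioral data (participant, block, cue
condition, correctness, RT in seconds) plus a per-participant trait
covariate table (AQ total score, 0-50).  Conditions follow the coding
neutral=1, valid=2, invalid=3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CONDITION_CODES",
    "StudyData",
    "BehavioralSummary",
    "read_trials",
    "write_trials",
    "filter_rts",
    "accuracy_code",
    "summarize_behavior",
    "fisher_ci",
]

CONDITION_CODES = {"neutral": 1, "valid": 2, "invalid": 3}
_CODE_LABELS = {v: k for k, v in CONDITION_CODES.items()}

TRIAL_COLUMNS = ["participant", "block", "condition", "correct", "rt"]
OPTIONAL_COLUMNS = ["stimulus_direction", "cue_direction"]

RT_MIN = 0.2  # s; trials strictly faster are removed
RT_MAX = 1.5  # s; trials strictly slower are removed


@dataclass
class StudyData:
    """Trial table plus per-participant covariates.

    ``trials`` columns: participant, block, condition (1/2/3), correct
    (bool), rt (s), and optionally stimulus_direction / cue_direction.
    ``covariates`` is indexed by participant with at least an ``aq``
    column; ``coherence`` is optional.
    """

    trials: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["aq"]))

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        if len(self.covariates) and "aq" in self.covariates:
            aq = self.covariates["aq"].dropna()
            if ((aq < 0) | (aq > 50)).any():
                raise ValueError("AQ scores must lie in [0, 50]")
            unknown = set(self.trials["participant"]) - set(self.covariates.index)
            if unknown:
                raise ValueError(
                    f"{len(unknown)} participants missing from covariate table, e.g. {sorted(unknown)[:3]}"
                )

    @property
    def participants(self) -> list:
        return sorted(self.trials["participant"].unique())

    def for_participant(self, pid) -> pd.DataFrame:
        return self.trials[self.trials["participant"] == pid]

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class BehavioralSummary:
    """Across-participant summaries per cue condition plus AQ correlations."""

    median_rt_mean: dict
    median_rt_sd: dict
    accuracy_mean: dict
    accuracy_sd: dict
    aq_correlations: pd.DataFrame  # rows (measure, condition); columns r, ci_low, ci_high, n

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond in ("neutral", "valid", "invalid"):
            rows.append(
                {
                    "condition": cond,
                    "median_rt_mean": self.median_rt_mean[cond],
                    "median_rt_sd": self.median_rt_sd[cond],
                    "accuracy_mean": self.accuracy_mean[cond],
                    "accuracy_sd": self.accuracy_sd[cond],
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        out = {
            "per_condition": self.to_frame().to_dict(orient="records"),
            "aq_correlations": self.aq_correlations.reset_index().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(out, indent=2, default=float))


class SchemaError(ValueError):
    """Input file violates the expected trial/covariate schema."""


def _parse_conditions(col: pd.Series) -> pd.Series:
    as_str = col.astype(str).str.strip().str.lower()
    mapped = as_str.map(CONDITION_CODES)
    numeric = pd.to_numeric(as_str, errors="coerce")
    mapped = mapped.fillna(numeric)
    bad = mapped.isna() | ~mapped.isin([1, 2, 3])
    if bad.any():
        labels = sorted(set(col[bad].astype(str)))
        raise SchemaError(f"unknown condition labels: {labels}")
    return mapped.astype(np.int64)


def read_trials(path, covariates_path=None, rt_unit: str = "s", sep=None) -> StudyData:
    """Read a delimited trial table (and optional covariate table).

    Parameters
    ----------
    path
        CSV/TSV with header: participant, block, condition, correct, rt
        (plus optional direction columns).  Delimiter is sniffed unless
        ``sep`` is given.
    covariates_path
        CSV with header participant, aq[, coherence].
    rt_unit
        's' (default) or 'ms'; ms values are converted to seconds.

    Raises :class:`SchemaError` listing offending rows/labels on
    malformed input.
    """
    if rt_unit not in ("s", "ms"):
        raise ValueError(f"rt_unit must be 's' or 'ms', got {rt_unit!r}")
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df["condition"] = _parse_conditions(df["condition"])
    rt = pd.to_numeric(df["rt"], errors="coerce")
    bad = rt.isna() | (rt <= 0)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # 1-based incl. header
        raise SchemaError(f"unparseable or non-positive RT in file lines: {rows[:20]}")
    df["rt"] = rt / 1000.0 if rt_unit == "ms" else rt
    df["correct"] = (
        df["correct"].astype(str).str.strip().str.lower().map(
            {"true": True, "false": False, "1": True, "0": False,
             "1.0": True, "0.0": False}
        )
    )
    if df["correct"].isna().any():
        raise SchemaError("correct column must be boolean (true/false or 0/1)")
    df["correct"] = df["correct"].astype(bool)
    df["block"] = df["block"].astype(np.int64)
    keep = TRIAL_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in df.columns]
    cov = pd.DataFrame(columns=["aq"])
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path)
        cov.columns = [c.strip().lower() for c in cov.columns]
        if "participant" not in cov.columns or "aq" not in cov.columns:
            raise SchemaError("covariate table needs 'participant' and 'aq' columns")
        cov = cov.set_index("participant")
    return StudyData(trials=df[keep].reset_index(drop=True), covariates=cov)


def write_trials(data: StudyData, path, covariates_path=None) -> None:
    """Write the trial table (and optionally covariates) as CSV."""
    out = data.trials.copy()
    out["condition"] = out["condition"].map(_CODE_LABELS)
    out.to_csv(path, index=False)
    if covariates_path is not None:
        data.covariates.reset_index(names="participant").to_csv(covariates_path, index=False)


def filter_rts(data: StudyData, lo: float = RT_MIN, hi: float = RT_MAX):
    """Remove implausibly fast/slow trials (rt < lo or rt > hi, bounds kept).

    Returns the filtered :class:`StudyData` and a retention report with
    per-participant retained counts and fractions plus the overall mean
    retained fraction (mean of per-participant percentages).
    """
    keep = (data.trials["rt"] >= lo) & (data.trials["rt"] <= hi)
    per = data.trials.groupby("participant", sort=True).apply(
        lambda g: pd.Series(
            {
                "n_total": len(g),
                "n_retained": int(((g["rt"] >= lo) & (g["rt"] <= hi)).sum()),
            }
        ),
        include_groups=False,
    )
    per["retention_pct"] = 100.0 * per["n_retained"] / per["n_total"]
    empty = per.index[per["n_retained"] == 0].tolist()
    if empty:
        import warnings

        warnings.warn(
            f"participants with zero retained trials (excluded from fitting): {empty}",
            stacklevel=2,
        )
    report = {
        "per_participant": per,
        "mean_retention_pct": float(per["retention_pct"].mean()),
        "min_retention_pct": float(per["retention_pct"].min()),
        "max_retention_pct": float(per["retention_pct"].max()),
        "excluded_participants": empty,
    }
    filtered = StudyData(
        trials=data.trials[keep].reset_index(drop=True), covariates=data.covariates
    )
    return filtered, report


def accuracy_code(data: StudyData) -> StudyData:
    """Collapse across stimulus directions: trials keyed by (condition, correct).

    Direction columns are retained as metadata but play no role in the
    likelihood; the upper diffusion boundary is the correct response.
    """
    trials = data.trials.copy()
    trials["boundary"] = np.where(trials["correct"], "upper", "lower")
    return StudyData(trials=trials, covariates=data.covariates)


def fisher_ci(r: float, n: int, level: float = 0.95):
    """Fisher-z confidence interval for a Pearson correlation."""
    if n < 4 or not np.isfinite(r) or abs(r) >= 1:
        return (np.nan, np.nan)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = stats.norm.ppf(0.5 + level / 2)
    return (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))


def summarize_behavior(data: StudyData) -> BehavioralSummary:
    """Mean/SD across participants of per-participant median correct RT and
    % accuracy, per cue condition, plus Pearson correlations with AQ.

    Participants without correct trials in a condition are dropped from
    that condition's RT cell (with a warning); correlations use Fisher-z
    95% CIs and are NaN when undefined (zero variance or n < 4).
    """
    import warnings

    per_measure = {}
    for code, cond in _CODE_LABELS.items():
        sub = data.trials[data.trials["condition"] == code]
        acc = sub.groupby("participant")["correct"].mean() * 100.0
        med = sub[sub["correct"]].groupby("participant")["rt"].median()
        dropped = set(acc.index) - set(med.index)
        if dropped:
            warnings.warn(
                f"no correct {cond} trials for participants {sorted(dropped)[:5]}; "
                "dropped from that RT cell",
                stacklevel=2,
            )
        per_measure[("median_rt", cond)] = med
        per_measure[("accuracy", cond)] = acc

    def _corr(series: pd.Series):
        if "aq" not in data.covariates.columns or len(data.covariates) == 0:
            return np.nan, (np.nan, np.nan), 0
        joined = pd.concat([series, data.covariates["aq"]], axis=1, join="inner").dropna()
        n = len(joined)
        x, y = joined.iloc[:, 0].to_numpy(float), joined.iloc[:, 1].to_numpy(float)
        if n < 4 or np.std(x) == 0 or np.std(y) == 0:
            warnings.warn("correlation undefined (constant input or n < 4)", stacklevel=3)
            return np.nan, (np.nan, np.nan), n
        r = float(np.corrcoef(x, y)[0, 1])
        return r, fisher_ci(r, n), n

    rows = {}
    for key, series in per_measure.items():
        r, (lo, hi), n = _corr(series)
        rows[key] = {"r": r, "ci_low": lo, "ci_high": hi, "n": n}
    corr = pd.DataFrame(rows).T
    corr.index.names = ["measure", "condition"]

    conds = list(_CODE_LABELS.values())
    return BehavioralSummary(
        median_rt_mean={c: float(per_measure[("median_rt", c)].mean()) for c in conds},
        median_rt_sd={c: float(per_measure[("median_rt", c)].std(ddof=1)) for c in conds},
        accuracy_mean={c: float(per_measure[("accuracy", c)].mean()) for c in conds},
        accuracy_sd={c: float(per_measure[("accuracy", c)].std(ddof=1)) for c in conds},
        aq_correlations=corr,
    )
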