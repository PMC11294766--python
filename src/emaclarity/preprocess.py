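"""Turn raw long-format EMA tables into analysis-ready indicators.

Implements the response-time screening rule (RTs < 0.2 s or > 30 s set to
missing), midpoint and person-mean dichotomization of the 0-100 sliders,
per-occasion median-RT clarity indicators (sign-flipped so higher = clearer),
the baseline-speed and symbol-search processing-speed covariates, and the
morning/midday/evening coding of prompt schedule position.

Times are milliseconds on disk and seconds in memory; conversion happens at
ingest only (`to_seconds`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RT_MIN",
    "RT_MAX",
    "ExclusionReport",
    "read_ema_csv",
    "to_seconds",
    "filter_rts",
    "dichotomize",
    "median_rt_indicators",
    "baseline_speed",
    "processing_speed",
    "code_time_of_day",
    "build_indicators",
]

RT_MIN = 0.2   # seconds; faster responses treated as careless
RT_MAX = 30.0  # seconds; slower responses treated as distraction
MIN_ITEMS_FOR_MEDIAN = 2  # a 1-item "median" is not a median


@dataclass(frozen=True)
class ExclusionReport:
    n_total: int
    n_flagged: int

    @property
    def fraction(self) -> float:
        return self.n_flagged / self.n_total if self.n_total else 0.0

    @property
    def percent(self) -> float:
        """Flagged share as a percentage rounded to 2 decimals."""
        return round(100.0 * self.fraction, 2)


def read_ema_csv(path) -> pd.DataFrame:
    """Read a long-format EMA CSV.

    The negative-affect valence code "NA" must not be parsed as missing, so
    only empty fields count as NA values.
    """
    return pd.read_csv(path, keep_default_na=False,
                       na_values=[""])


def to_seconds(df: pd.DataFrame, ms_col: str = "rt_ms",
               out_col: str = "rt") -> pd.DataFrame:
    """Add an RT column in seconds from the on-disk milliseconds column."""
    df = df.copy()
    df[out_col] = df[ms_col].astype(float) / 1000.0
    return df


def filter_rts(records: pd.DataFrame, rt_col: str = "rt",
               lo: float = RT_MIN, hi: float = RT_MAX):
    """Set implausibly fast/slow RTs to missing.

    Returns ``(records', ExclusionReport)``.  Negative RTs are corrupt input
    (distinct from outliers) and raise.
    """
    rt = records[rt_col]
    if (rt.dropna() < 0).any():
        raise ValueError("negative response times indicate corrupt input")
    records = records.copy()
    valid = rt.notna()
    flag = valid & ((rt < lo) | (rt > hi))
    records.loc[flag, rt_col] = np.nan
    return records, ExclusionReport(n_total=int(valid.sum()),
                                    n_flagged=int(flag.sum()))


def dichotomize(records: pd.DataFrame, rule: str = "scale_midpoint",
                response_col: str = "response_0_100") -> pd.DataFrame:
    """Binary-code slider responses.

    ``scale_midpoint``: response >= 50 -> 1 (at-or-above convention).
    ``person_mean``: threshold is the person's mean response for that
    valence across all occasions; ties again coded 1.  Persons with a single
    observation for a valence are flagged in the ``dichot_flagged`` column
    (the threshold then equals the observation, which is coded 1).
    """
    resp = records[response_col]
    if resp.isna().any() or (resp < 0).any() or (resp > 100).any():
        raise ValueError("responses must lie in [0, 100]")
    records = records.copy()
    if rule == "scale_midpoint":
        records["dichot"] = (resp >= 50).astype(int)
        records["dichot_flagged"] = False
    elif rule == "person_mean":
        grp = records.groupby(["person_id", "valence"])[response_col]
        thr = grp.transform("mean")
        n_obs = grp.transform("size")
        records["dichot"] = (resp >= thr).astype(int)
        records["dichot_flagged"] = (n_obs == 1).to_numpy()
    else:
        raise ValueError(f"unknown dichotomization rule {rule!r}")
    return records


def median_rt_indicators(records: pd.DataFrame,
                         min_items: int = MIN_ITEMS_FOR_MEDIAN) -> pd.DataFrame:
    """Per-occasion, per-valence sign-flipped median RT plus summaries.

    RTs must already be filtered.  The median is taken over available
    (non-missing) item RTs and multiplied by -1; it is missing when fewer
    than ``min_items`` of the valence's items have a usable RT.

    Returns a wide table with one row per person x occasion: na_rt, pa_rt
    (<= 0 when present), na_mean, pa_mean (mean slider 0-100), and
    na_dichot_sum, pa_dichot_sum when a ``dichot`` column is present.
    """
    aff = records[records["valence"].isin(["NA", "PA"])]
    keys = ["person_id", "occasion_id"]
    out = aff.groupby(keys, sort=True)["slot"].first().reset_index()
    for val in ("NA", "PA"):
        sub = aff[aff["valence"] == val]
        g = sub.groupby(keys, sort=True)
        pre = val.lower()
        med = -g["rt"].median()
        med[g["rt"].count() < min_items] = np.nan
        cols = {f"{pre}_rt": med, f"{pre}_mean": g["response_0_100"].mean()}
        if "dichot" in sub.columns:
            cols[f"{pre}_dichot_sum"] = g["dichot"].sum().astype("Int64")
        out = out.merge(pd.DataFrame(cols).reset_index(), on=keys, how="left")
    return out


def baseline_speed(records: pd.DataFrame,
                   baseline_valence: str = "BASE") -> pd.DataFrame:
    """Per-person median of the (filtered) baseline-item RTs, in seconds.

    Persons whose baseline RTs were all screened out keep a missing
    covariate but remain in the table.
    """
    base = records[records["valence"] == baseline_valence]
    if base.empty:
        raise ValueError("no baseline-item rows found")
    out = base.groupby("person_id")["rt"].median().rename("base_speed")
    persons = records[["person_id"]].drop_duplicates()
    return persons.merge(out, on="person_id", how="left")


def processing_speed(sessions: pd.DataFrame, n_trials: int = 20,
                     min_accurate: int = 14) -> pd.DataFrame:
    """Symbol-search processing speed per person.

    A session scores the median RT (seconds) of its accurate trials but only
    when at least ``min_accurate`` of ``n_trials`` were accurate; the person
    score is the mean of valid session scores, multiplied by -1 so that
    higher values indicate faster processing speed.
    """
    sizes = sessions.groupby(["person_id", "occasion_id"]).size()
    if (sizes != n_trials).any():
        bad = sizes[sizes != n_trials].index[0]
        raise ValueError(f"session {bad} does not have {n_trials} trials")
    df = to_seconds(sessions) if "rt" not in sessions else sessions

    def score(g: pd.DataFrame) -> float:
        acc = g[g["accurate"] == 1]
        if len(acc) < min_accurate:
            return np.nan
        return acc["rt"].median()

    sess = df.groupby(["person_id", "occasion_id"], sort=True).apply(
        score, include_groups=False).rename("session_score").reset_index()
    per = sess.groupby("person_id")["session_score"].mean()
    out = (-per).rename("proc_speed").reset_index()
    n_valid = sess.dropna(subset=["session_score"]).groupby("person_id").size()
    out["n_valid_sessions"] = out["person_id"].map(n_valid).fillna(0).astype(int)
    out.loc[out["n_valid_sessions"] == 0, "proc_speed"] = np.nan
    return out


def code_time_of_day(records: pd.DataFrame,
                     prompts_per_day: pd.Series | dict | None = None) -> pd.DataFrame:
    """Label each row morning / midday / evening from its schedule position.

    The first prompt of the day is morning, the last *scheduled* prompt of
    the person's day is evening (whether or not it was answered), everything
    between is midday.  ``prompts_per_day`` maps person_id to the scheduled
    number of daily prompts; when omitted it is inferred as the maximum
    observed prompt index per person.
    """
    records = records.copy()
    if prompts_per_day is None:
        ppd = records.groupby("person_id")["prompt_idx"].max()
    else:
        ppd = pd.Series(prompts_per_day)
    last = records["person_id"].map(ppd)
    if (records["prompt_idx"] > last).any():
        raise ValueError("prompt_idx exceeds the person's scheduled prompts per day")
    slot = np.full(len(records), "midday", dtype=object)
    slot[records["prompt_idx"].to_numpy() == 1] = "morning"
    slot[(records["prompt_idx"] == last).to_numpy()] = "evening"
    records["slot"] = slot
    return records


def build_indicators(ema: pd.DataFrame, dichot_rule: str = "scale_midpoint",
                     prompts_per_day=None):
    """Full preprocessing chain: seconds -> RT filter -> slots -> dichotomize
    -> per-occasion indicators + person covariates.

    Returns ``(indicators, covariates, report)``.
    """
    df = to_seconds(ema)
    df, report = filter_rts(df)
    if "slot" not in df.columns:
        df = code_time_of_day(df, prompts_per_day)
    aff = df[df["valence"].isin(["NA", "PA"])].copy()
    aff = dichotomize(aff, rule=dichot_rule)
    ind = median_rt_indicators(aff)
    cov = baseline_speed(df)
    return ind, cov, report
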