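"""Synthetic ecological momentary assessment (EMA) study generator.

Emulates a two-week intensive EMA protocol: ~196 adults answer 5-6 prompts a
day at 3-hour intervals, each prompt containing 4 negative-affect (NA) and 4
positive-affect (PA) slider items (0-100), a baseline multiple-choice
activity item, and a 20-trial symbol-search processing-speed task.  Item
response times follow a Wiener decision process (non-decision time plus
first-passage time), with person- and occasion-level heterogeneity in drift
level and response caution, prompt-level missingness, and implausibly
fast/slow RT artifacts.  Full ground truth is retained so that downstream
estimators can be tested for parameter recovery.

The latent structure (one occasion drift level theta per prompt, shared by
both valences through mirrored item difficulties) is:

    theta_pt     = u_p + kappa_p * delta_t,   delta_t ~ N(0, 1)
    log alpha_pt ~ N(log alpha_p, sd_logalpha_occ)

where ``kappa_p`` scales how far a person's momentary state strays from the
item difficulties: larger kappa means larger |theta - b| on average, faster
and more decisive answers, and hence higher "clarity" on both RT-based
indicators.  Slider responses are generated from the latent endorsement
propensity so that midpoint dichotomization recovers the latent binary
choice with high probability.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .wiener import sample_fpt, simulate_item_trial  # noqa: F401 (re-export)

__all__ = [
    "StudyDesign",
    "GeneratorParams",
    "TraitSpec",
    "default_item_difficulties",
    "default_trait_specs",
    "simulate_study",
    "attach_traits",
    "inject_artifacts",
    "simulate_symbol_search",
    "write_study",
    "read_study",
]

NA_ITEMS = ["tense", "upset", "sad", "disappointed"]
PA_ITEMS = ["happy", "content", "enthusiastic", "excited"]
BASELINE_ITEM = "baseline_activity"


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of the EMA protocol."""

    n_persons: int = 196
    n_days: int = 14
    prompts_per_day: int = 6        # persons may be assigned 5 instead (early sleepers)
    inter_prompt_hours: float = 3.0
    items_per_valence: int = 4
    frac_five_prompt: float = 0.3   # fraction of persons on the 5-prompt schedule

    def __post_init__(self):
        for name in ("n_persons", "n_days", "prompts_per_day", "items_per_valence"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.prompts_per_day not in (5, 6):
            raise ValueError("prompts_per_day must be 5 or 6")
        if not 0 <= self.frac_five_prompt <= 1:
            raise ValueError("frac_five_prompt must be in [0, 1]")


@dataclass(frozen=True)
class GeneratorParams:
    """Population parameters of the generative diffusion process.

    Dispersion defaults were calibrated once so that the intraclass
    correlation of the generated log absolute drift is ~0.27 (between-person
    share of variance typical for occasion-level clarity indicators).
    """

    mu_u_theta: float = 0.0
    sd_u_theta: float = 0.55        # between-person SD of mean drift level
    mu_log_kappa: float = 0.0       # person clarity scale, lognormal
    sd_log_kappa: float = 0.55
    sd_delta: float = 1.0           # occasion drift dispersion multiplier base
    mu_log_alpha: float = float(np.log(2.0))
    sd_log_alpha_person: float = 0.20
    sd_log_alpha_occ: float = 0.15
    ter_min: float = 0.25           # non-decision time, uniform range (s)
    ter_max: float = 0.45
    mu_log_base_speed: float = float(np.log(0.5))  # baseline responding offset (s)
    sd_log_base_speed: float = 0.35
    mu_proc_speed: float = 2.0      # symbol-search median RT scale (s)
    sd_proc_speed: float = 0.4
    rho_speed: float = 0.5          # shared general-speed factor loading
    slider_noise_sd: float = 0.08
    fixed_kappa: float | None = None  # set 0 for the degenerate no-clarity-variation case

    def validate(self):
        if self.fixed_kappa is not None and self.fixed_kappa < 0:
            raise ValueError("population dispersion 'fixed_kappa' must be non-negative")
        for name in ("sd_u_theta", "sd_log_kappa", "sd_delta",
                     "sd_log_alpha_person", "sd_log_alpha_occ",
                     "sd_log_base_speed", "sd_proc_speed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"population dispersion {name!r} must be positive")
        if not (0 < self.ter_min <= self.ter_max):
            raise ValueError("require 0 < ter_min <= ter_max")


@dataclass(frozen=True)
class TraitSpec:
    """Target between-person correlation of a trait with latent clarity."""

    trait_name: str
    target_corr: float
    noise_sd: float | None = None   # default sqrt(1 - r^2): exact target correlation

    def __post_init__(self):
        if abs(self.target_corr) > 1:
            raise ValueError(f"|target_corr| must be <= 1 for {self.trait_name}")


def default_item_difficulties() -> dict[str, np.ndarray]:
    """Item difficulties in logits; PA set mirrors the NA set."""
    na = np.array([-1.0, -0.3, 0.4, 1.1])
    return {"NA": na, "PA": -na[::-1]}


def default_trait_specs() -> list[TraitSpec]:
    """Trait panel with between-person correlations to latent NA clarity.

    Magnitudes mirror the size of associations typically reported for
    clarity indicators (e.g. depression/anxiety around -0.27).
    """
    r = {
        "life_satisfaction": 0.10,
        "neuroticism": -0.18,
        "depression": -0.27,
        "anxiety": -0.27,
        "diabetes_distress": -0.17,
        "ders_total": -0.15,
        "ders_strategies": -0.15,
        "ders_nonacceptance": -0.10,
        "ders_impulse": 0.02,
        "ders_goals": -0.07,
        "ders_awareness": -0.18,
        "ders_clarity": -0.11,
    }
    return [TraitSpec(k, v) for k, v in r.items()]


def _person_latents(design: StudyDesign, pop: GeneratorParams,
                    rng: np.random.Generator) -> pd.DataFrame:
    n = design.n_persons
    g_speed = rng.standard_normal(n)  # shared general-speed factor
    persons = pd.DataFrame({
        "person_id": np.arange(1, n + 1),
        "u_theta": pop.mu_u_theta + pop.sd_u_theta * rng.standard_normal(n),
        "kappa": (np.full(n, float(pop.fixed_kappa)) if pop.fixed_kappa is not None
                  else np.exp(pop.mu_log_kappa
                              + pop.sd_log_kappa * rng.standard_normal(n))),
        "log_alpha_mean": pop.mu_log_alpha
        + pop.sd_log_alpha_person * rng.standard_normal(n),
        "ter": rng.uniform(pop.ter_min, pop.ter_max, n),
        "base_speed": np.exp(
            pop.mu_log_base_speed
            + pop.sd_log_base_speed
            * (pop.rho_speed * g_speed
               + np.sqrt(1 - pop.rho_speed ** 2) * rng.standard_normal(n))),
        "proc_speed": pop.mu_proc_speed
        + pop.sd_proc_speed
        * (pop.rho_speed * g_speed
           + np.sqrt(1 - pop.rho_speed ** 2) * rng.standard_normal(n)),
        "prompts_per_day": np.where(
            rng.random(n) < design.frac_five_prompt, 5, design.prompts_per_day
        ).astype(int),
    })
    persons["proc_speed"] = persons["proc_speed"].clip(lower=0.5)
    return persons


def _slot_labels(prompt_idx: np.ndarray, ppd: np.ndarray) -> np.ndarray:
    out = np.full(prompt_idx.shape, "midday", dtype=object)
    out[prompt_idx == 1] = "morning"
    out[prompt_idx == ppd] = "evening"
    return out


def latent_log_absolute_drift(occasions: pd.DataFrame,
                              item_difficulties: dict[str, np.ndarray] | None = None,
                              valence: str = "NA",
                              floor: float = 1e-6) -> np.ndarray:
    """Ground-truth occasion log absolute drift, mean_i |theta - b_i|."""
    if item_difficulties is None:
        item_difficulties = default_item_difficulties()
    b = np.asarray(item_difficulties[valence], float)
    theta = occasions["theta"].to_numpy()
    ad = np.mean(np.abs(theta[:, None] - b[None, :]), axis=1)
    return np.log(np.maximum(ad, floor))


def simulate_study(design: StudyDesign | None = None,
                   pop_params: GeneratorParams | None = None,
                   item_difficulties: dict[str, np.ndarray] | None = None,
                   seed: int = 0):
    """Generate a complete synthetic EMA study.

    Returns
    -------
    ema : DataFrame
        Long format, one row per person x prompt x item (both valences plus
        the baseline activity item); columns person_id, day, prompt_idx,
        occasion_id, slot, item_id, valence, response_0_100, rt_ms.
    truth : dict of DataFrames
        "persons" (true person parameters incl. schedule) and "occasions"
        (true occasion drift level and boundary).
    """
    design = design or StudyDesign()
    pop = pop_params or GeneratorParams()
    pop.validate()
    items = item_difficulties or default_item_difficulties()
    for val in ("NA", "PA"):
        if len(items[val]) != design.items_per_valence:
            raise ValueError(f"need {design.items_per_valence} {val} difficulties")
    rng = np.random.default_rng(seed)
    persons = _person_latents(design, pop, rng)

    # occasion grid
    rows = []
    for _, p in persons.iterrows():
        ppd = int(p.prompts_per_day)
        for day in range(1, design.n_days + 1):
            for prm in range(1, ppd + 1):
                rows.append((int(p.person_id), day, prm, ppd))
    occ = pd.DataFrame(rows, columns=["person_id", "day", "prompt_idx",
                                      "prompts_per_day"])
    occ["occasion_id"] = occ["day"] * 10 + occ["prompt_idx"]
    occ = occ.merge(persons[["person_id", "u_theta", "kappa", "log_alpha_mean",
                             "ter", "base_speed"]], on="person_id")
    n_occ = len(occ)
    occ["theta"] = (occ["u_theta"]
                    + occ["kappa"] * pop.sd_delta * rng.standard_normal(n_occ))
    occ["log_alpha"] = (occ["log_alpha_mean"]
                        + pop.sd_log_alpha_occ * rng.standard_normal(n_occ))
    occ["slot"] = _slot_labels(occ["prompt_idx"].to_numpy(),
                               occ["prompts_per_day"].to_numpy())

    # affect items: vectorized Wiener draws across all occasion x item cells
    ema_parts = []
    for val, names in (("NA", NA_ITEMS), ("PA", PA_ITEMS)):
        b = np.asarray(items[val], float)
        names = names[: design.items_per_valence]
        if len(names) < design.items_per_valence:
            names = names + [f"{val.lower()}_{j}" for j in
                             range(len(names), design.items_per_valence)]
        theta = np.repeat(occ["theta"].to_numpy(), len(b))
        A = np.repeat(np.exp(occ["log_alpha"].to_numpy()), len(b))
        ter = np.repeat((occ["ter"] + occ["base_speed"]).to_numpy(), len(b))
        bb = np.tile(b, n_occ)
        choice, rt = sample_fpt(theta - bb, A, ter, rng)
        # slider from latent endorsement propensity; midpoint dichotomization
        # recovers the latent choice with high probability
        from scipy.special import expit
        prop = expit(A * (theta - bb))
        slider = np.round(100 * np.clip(
            prop + pop.slider_noise_sd * rng.standard_normal(prop.size), 0, 1))
        part = pd.DataFrame({
            "person_id": np.repeat(occ["person_id"].to_numpy(), len(b)),
            "day": np.repeat(occ["day"].to_numpy(), len(b)),
            "prompt_idx": np.repeat(occ["prompt_idx"].to_numpy(), len(b)),
            "occasion_id": np.repeat(occ["occasion_id"].to_numpy(), len(b)),
            "slot": np.repeat(occ["slot"].to_numpy(), len(b)),
            "item_id": np.tile(np.array(names, dtype=object), n_occ),
            "valence": val,
            "response_0_100": slider.astype(int),
            "rt_ms": np.round(rt * 1000).astype(int),
        })
        ema_parts.append(part)

    # baseline activity item: lognormal around the person's base speed
    base_rt = (occ["base_speed"].to_numpy()
               * np.exp(0.4 * rng.standard_normal(n_occ)) + 0.3)
    base = pd.DataFrame({
        "person_id": occ["person_id"], "day": occ["day"],
        "prompt_idx": occ["prompt_idx"], "occasion_id": occ["occasion_id"],
        "slot": occ["slot"], "item_id": BASELINE_ITEM, "valence": "BASE",
        "response_0_100": rng.integers(0, 8, n_occ),
        "rt_ms": np.round(base_rt * 1000).astype(int),
    })
    ema_parts.append(base)
    ema = pd.concat(ema_parts, ignore_index=True)
    ema = ema.sort_values(
        ["person_id", "day", "prompt_idx", "valence", "item_id"],
        kind="mergesort").reset_index(drop=True)

    truth_occ = occ[["person_id", "day", "prompt_idx", "occasion_id", "slot",
                     "theta", "log_alpha"]].copy()
    truth_occ["log_ad_na"] = latent_log_absolute_drift(truth_occ, items, "NA")
    truth_occ["log_ad_pa"] = latent_log_absolute_drift(truth_occ, items, "PA")
    return ema, {"persons": persons, "occasions": truth_occ}


def attach_traits(truth: dict, specs: Sequence[TraitSpec] | None = None,
                  seed: int = 0,
                  clarity_col: str = "log_ad_na") -> pd.DataFrame:
    """Person-level trait table with known correlations to latent clarity.

    Each trait is ``r * Z + s * eps`` where Z is the standardized person mean
    of the latent log absolute drift and s defaults to sqrt(1 - r^2), making
    the population correlation exactly the target.
    """
    specs = list(default_trait_specs() if specs is None else specs)
    persons = truth["persons"]
    if len(persons) < 3:
        raise ValueError("need at least 3 persons to attach traits")
    occ = truth["occasions"]
    pm = occ.groupby("person_id")[clarity_col].mean()
    z = (pm - pm.mean()) / pm.std(ddof=0)
    rng = np.random.default_rng(seed)
    out = pd.DataFrame({"person_id": pm.index.to_numpy()})
    zv = z.to_numpy()
    for spec in specs:
        r = spec.target_corr
        s = np.sqrt(max(1.0 - r ** 2, 0.0)) if spec.noise_sd is None else spec.noise_sd
        out[spec.trait_name] = r * zv + s * rng.standard_normal(zv.size)
    return out


def inject_artifacts(ema: pd.DataFrame, missing_prompt_rate: float = 0.08,
                     fast_rt_rate: float = 0.01, slow_rt_rate: float = 0.003,
                     seed: int = 0):
    """Drop whole prompts and plant implausible RTs.

    Returns ``(ema', flags)`` where flags records per-row artifact provenance
    ("fast"/"slow") and the set of dropped prompts.
    """
    for name, r in (("missing_prompt_rate", missing_prompt_rate),
                    ("fast_rt_rate", fast_rt_rate),
                    ("slow_rt_rate", slow_rt_rate)):
        if not 0 <= r < 1:
            raise ValueError(f"{name} must be in [0, 1)")
    if fast_rt_rate + slow_rt_rate >= 1:
        raise ValueError("fast_rt_rate + slow_rt_rate must be < 1")
    rng = np.random.default_rng(seed)
    ema = ema.copy()
    prompts = ema[["person_id", "day", "prompt_idx"]].drop_duplicates()
    drop = prompts[rng.random(len(prompts)) < missing_prompt_rate]
    key = ema.merge(drop.assign(_drop=True), how="left",
                    on=["person_id", "day", "prompt_idx"])["_drop"].notna()
    ema = ema.loc[~key.to_numpy()].reset_index(drop=True)

    u = rng.random(len(ema))
    fast = u < fast_rt_rate
    slow = (u >= fast_rt_rate) & (u < fast_rt_rate + slow_rt_rate)
    rt = ema["rt_ms"].to_numpy().astype(float)
    rt[fast] = rng.uniform(10, 190, fast.sum())       # < 0.2 s
    rt[slow] = rng.uniform(31000, 60000, slow.sum())  # > 30 s
    ema["rt_ms"] = np.round(rt).astype(int)
    flags = pd.DataFrame({"artifact": np.where(fast, "fast",
                                               np.where(slow, "slow", "none"))})
    return ema, {"row_flags": flags, "dropped_prompts": drop.reset_index(drop=True)}


def simulate_symbol_search(truth: dict, n_trials: int = 20,
                           accuracy: float = 0.92, seed: int = 0) -> pd.DataFrame:
    """20-trial symbol-search sessions, one per EMA occasion.

    Per-trial RT is lognormal around the person's latent processing speed;
    accuracy is Bernoulli.
    """
    rng = np.random.default_rng(seed)
    occ = truth["occasions"][["person_id", "occasion_id"]]
    persons = truth["persons"].set_index("person_id")
    ps = persons.loc[occ["person_id"], "proc_speed"].to_numpy()
    n = len(occ) * n_trials
    rt = np.repeat(ps, n_trials) * np.exp(0.25 * rng.standard_normal(n))
    acc = (rng.random(n) < accuracy).astype(int)
    return pd.DataFrame({
        "person_id": np.repeat(occ["person_id"].to_numpy(), n_trials),
        "occasion_id": np.repeat(occ["occasion_id"].to_numpy(), n_trials),
        "trial_idx": np.tile(np.arange(1, n_trials + 1), len(occ)),
        "accurate": acc,
        "rt_ms": np.round(rt * 1000).astype(int),
    })


# ---------------------------------------------------------------------------
# I/O: plain CSV plus a manifest recording seed and config hash.
# ---------------------------------------------------------------------------

def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_study(out_dir, ema: pd.DataFrame, truth: dict,
                traits: pd.DataFrame | None = None,
                symbol: pd.DataFrame | None = None,
                seed: int | None = None, config: dict | None = None):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ema.to_csv(out / "ema.csv", index=False)
    truth["persons"].to_csv(out / "truth_persons.csv", index=False)
    truth["occasions"].to_csv(out / "truth_occasions.csv", index=False)
    if traits is not None:
        traits.to_csv(out / "traits.csv", index=False)
    if symbol is not None:
        symbol.to_csv(out / "symbol_search.csv", index=False)
    manifest = {"seed": seed, "config": config,
                "config_hash": _config_hash(config or {}),
                "files": sorted(p.name for p in out.glob("*.csv"))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def read_study(in_dir):
    p = Path(in_dir)
    out = {"ema": pd.read_csv(p / "ema.csv", keep_default_na=False, na_values=[""])}
    for key, name in (("persons", "truth_persons.csv"),
                      ("occasions", "truth_occasions.csv"),
                      ("traits", "traits.csv"),
                      ("symbol", "symbol_search.csv")):
        f = p / name
        if f.exists():
            out[key] = pd.read_csv(f)
    return out
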