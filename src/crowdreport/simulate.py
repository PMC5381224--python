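"""Synthetic method-of-adjustment trial data.

The study's raw trials are not deposited, so every analysis stage is
validated on data generated here with the experiment's statistical
structure: flanker-gap orientations sampled from a normal distribution
centred on the target with SD 22.5 deg (the two-gap condition adds a second
gap centred 180 deg from the first, same SD), targets uniform on the circle,
and reports drawn from a mixture of strategies — accurate target report,
weighted average of target and near gap, substitution of the near or far
gap, or a uniform guess — with circular noise on all but the guess.

Ground-truth component labels are stored alongside each synthetic report so
recovery studies can score estimators per trial; real-data tables would
simply lack the ``truth_label`` column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .circular import wrap_deg, wrap360
from .design import (
    UNFLANKED, NO_GAP, ONE_GAP, TWO_GAP,
    Condition, ExperimentDesign, enumerate_conditions,
)
from .mixture import circ_sd_to_kappa

__all__ = [
    "COMPONENTS",
    "TRIAL_COLUMNS",
    "ObserverModel",
    "sample_flanker_gaps",
    "simulate_report",
    "simulate_experiment",
    "simulate_validation_dataset",
]

# generative report strategies
COMPONENTS = ("target", "average", "sub_near", "sub_far", "guess")

# canonical trial-table schema (degrees throughout; NaN for absent gaps)
TRIAL_COLUMNS = [
    "observer_id", "session", "flanker_type", "edge_separation_deg",
    "target_deg", "gap1_deg", "gap2_deg", "report_deg",
    "error_deg", "delta1_deg", "delta2_deg", "truth_label",
]


@dataclass(frozen=True)
class ObserverModel:
    """Generative mixture over report strategies.

    ``average_weight`` w interpolates along the short arc from target (w=0)
    to the near flanker gap (w=1). ``noise_sd_deg`` is the circular noise SD
    applied to every component except the (already uniform) guess;
    ``noise_family`` selects wrapped-normal or von Mises noise — at
    SD <~ 30 deg the two are nearly indistinguishable.

    Components that require a gap the condition does not supply receive zero
    effective probability and the rest are renormalised.
    """

    p_target: float = 1.0
    p_average: float = 0.0
    p_sub_near: float = 0.0
    p_sub_far: float = 0.0
    p_guess: float = 0.0
    average_weight: float = 0.5
    noise_sd_deg: float = 10.0
    noise_family: str = "von_mises"

    def __post_init__(self):
        probs = self.probabilities
        if any(not 0.0 <= p <= 1.0 for p in probs.values()):
            raise ValueError("component probabilities must lie in [0, 1]")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("component probabilities must sum to 1")
        if not 0.0 <= self.average_weight <= 1.0:
            raise ValueError("average_weight must lie in [0, 1]")
        if self.noise_sd_deg <= 0:
            raise ValueError("noise_sd_deg must be positive")
        if self.noise_family not in ("wrapped_normal", "von_mises"):
            raise ValueError("noise_family must be 'wrapped_normal' or 'von_mises'")

    @property
    def probabilities(self) -> dict[str, float]:
        return {
            "target": self.p_target, "average": self.p_average,
            "sub_near": self.p_sub_near, "sub_far": self.p_sub_far,
            "guess": self.p_guess,
        }

    def effective_probabilities(self, flanker_type: str) -> dict[str, float]:
        """Probabilities renormalised for the components the condition supports."""
        probs = dict(self.probabilities)
        if flanker_type in (UNFLANKED, NO_GAP):
            probs["average"] = probs["sub_near"] = probs["sub_far"] = 0.0
        elif flanker_type == ONE_GAP:
            probs["sub_far"] = 0.0
        total = sum(probs.values())
        if total <= 0:
            raise ValueError(
                f"observer model places all probability on components absent in "
                f"'{flanker_type}' trials"
            )
        return {k: v / total for k, v in probs.items()}

    def to_dict(self) -> dict:
        return asdict(self)


def sample_flanker_gaps(target_deg, condition: Condition,
                        design: ExperimentDesign, rng: np.random.Generator):
    """Draw flanker-gap orientation(s) for one or many trials.

    one_gap:  gap1 = target + N(0, sd)            (sd = 22.5 deg by default)
    two_gap:  additionally gap2 = gap1 + N(180, sd)
    no_gap / unflanked: (None, None).

    Accepts a scalar or an array of targets; returns orientations wrapped to
    [0, 360), matching the input shape.
    """
    if condition.flanker_type in (UNFLANKED, NO_GAP):
        return None, None
    t = np.asarray(target_deg, dtype=float)
    sd = design.flanker_offset_sd_deg
    gap1 = wrap360(t + rng.normal(0.0, sd, size=t.shape) if sd > 0 else t)
    if condition.flanker_type == ONE_GAP:
        return gap1, None
    gap2 = wrap360(gap1 + rng.normal(design.far_gap_center_deg, sd, size=t.shape)
                   if sd > 0 else gap1 + design.far_gap_center_deg)
    return gap1, gap2


_KAPPA_CACHE: dict[float, float] = {}


def _circular_noise(model: ObserverModel, size, rng: np.random.Generator) -> np.ndarray:
    if model.noise_family == "wrapped_normal":
        return rng.normal(0.0, model.noise_sd_deg, size=size)
    kappa = _KAPPA_CACHE.get(model.noise_sd_deg)
    if kappa is None:
        kappa = _KAPPA_CACHE[model.noise_sd_deg] = circ_sd_to_kappa(model.noise_sd_deg)
    return np.degrees(rng.vonmises(0.0, kappa, size=size))


def simulate_report(target_deg: float, gap1_deg, gap2_deg,
                    model: ObserverModel, flanker_type: str,
                    rng: np.random.Generator) -> tuple[float, str]:
    """Simulate one report; returns (report_deg in [0,360), component label).

    Component means: target -> target orientation; average -> short-arc
    interpolation target + w*delta1; sub_near -> gap1; sub_far -> gap2;
    guess -> uniform. Circular noise is added to all but the guess.
    """
    probs = model.effective_probabilities(flanker_type)
    names = list(probs)
    comp = rng.choice(names, p=[probs[n] for n in names])
    if comp == "guess":
        return float(rng.uniform(0.0, 360.0)), comp
    if comp == "target":
        mean = target_deg
    elif comp == "average":
        mean = target_deg + model.average_weight * wrap_deg(gap1_deg - target_deg)
    elif comp == "sub_near":
        mean = gap1_deg
    else:  # sub_far
        mean = gap2_deg
    noise = float(_circular_noise(model, None, rng))
    return wrap360(mean + noise), comp


def _derive(df: pd.DataFrame) -> pd.DataFrame:
    """Fill wrapped error and delta columns from the raw orientations."""
    df = df.copy()
    df["error_deg"] = wrap_deg((df["report_deg"] - df["target_deg"]).to_numpy())
    for gap, delta in (("gap1_deg", "delta1_deg"), ("gap2_deg", "delta2_deg")):
        vals = np.full(len(df), np.nan)
        ok = df[gap].notna().to_numpy()
        if ok.any():
            vals[ok] = wrap_deg((df.loc[ok, gap] - df.loc[ok, "target_deg"]).to_numpy())
        df[delta] = vals
    return df


def simulate_experiment(design: ExperimentDesign, model: ObserverModel,
                        observer_id: str = "S1", seed=None) -> pd.DataFrame:
    """Simulate a full experiment for one observer.

    Emits ``n_sessions x n_conditions x reps`` trials (1600 for the default
    design: 320 per session, 100 per condition), with the target orientation
    uniform on [0, 360) and trial order shuffled within each session. Fully
    reproducible from ``seed``; derived error/delta columns are filled.
    """
    rng = np.random.default_rng(seed)
    conditions = enumerate_conditions(design)
    rows = []
    for session in range(1, design.n_sessions + 1):
        session_rows = []
        for cond in conditions:
            for _ in range(design.reps_per_condition_per_session):
                target = float(rng.uniform(0.0, 360.0))
                gap1, gap2 = sample_flanker_gaps(target, cond, design, rng)
                g1 = float(gap1) if gap1 is not None else np.nan
                g2 = float(gap2) if gap2 is not None else np.nan
                report, comp = simulate_report(target, g1, g2, model,
                                               cond.flanker_type, rng)
                session_rows.append({
                    "observer_id": observer_id, "session": session,
                    "flanker_type": cond.flanker_type,
                    "edge_separation_deg": cond.edge_separation_deg,
                    "target_deg": target, "gap1_deg": g1, "gap2_deg": g2,
                    "report_deg": report, "truth_label": comp,
                })
        order = rng.permutation(len(session_rows))
        rows.extend(session_rows[i] for i in order)
    df = pd.DataFrame(rows)
    df["edge_separation_deg"] = df["edge_separation_deg"].astype(float)
    return _derive(df)[TRIAL_COLUMNS]


def simulate_validation_dataset(p_target: float, p_substitution: float,
                                noise_sd_deg: float, n_trials: int = 100,
                                seed=None, design: ExperimentDesign | None = None,
                                fixed_delta_deg: float | None = None,
                                noise_family: str = "wrapped_normal") -> pd.DataFrame:
    """The estimator-validation design: a one-gap-style two-component dataset.

    Reports are target reports or substitutions of the flanker gap, each
    plus Gaussian (wrapped-normal, by default) noise; 100 trials matches one
    condition's worth of data in the experiment. Flanker offsets are drawn
    from the experimental 22.5-deg-SD distribution unless ``fixed_delta_deg``
    pins them. Ground-truth labels are recorded per trial.
    """
    if abs(p_target + p_substitution - 1.0) > 1e-9:
        raise ValueError("p_target + p_substitution must equal 1")
    if not 0.0 <= p_target <= 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    design = design or ExperimentDesign()
    model = ObserverModel(p_target=p_target, p_sub_near=p_substitution,
                          noise_sd_deg=noise_sd_deg, noise_family=noise_family)
    rng = np.random.default_rng(seed)
    cond = Condition(ONE_GAP, design.edge_separations_deg[0])
    rows = []
    for _ in range(n_trials):
        target = float(rng.uniform(0.0, 360.0))
        if fixed_delta_deg is None:
            gap1, _ = sample_flanker_gaps(target, cond, design, rng)
            gap1 = float(gap1)
        else:
            gap1 = wrap360(target + fixed_delta_deg)
        report, comp = simulate_report(target, gap1, np.nan, model, ONE_GAP, rng)
        rows.append({
            "observer_id": "sim", "session": 1, "flanker_type": ONE_GAP,
            "edge_separation_deg": cond.edge_separation_deg,
            "target_deg": target, "gap1_deg": gap1, "gap2_deg": np.nan,
            "report_deg": report, "truth_label": comp,
        })
    return _derive(pd.DataFrame(rows))[TRIAL_COLUMNS]
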