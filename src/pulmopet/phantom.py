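"""Synthetic lung-phantom and tracer simulator.

Generates seeded study bundles (animals x conditions x 30 ROIs x 2 tracers)
whose statistical structure mirrors a two-condition (baseline / endotoxin
lung-injury) dynamic-PET perfusion study in supine large animals:

* vertical perfusion gradients — a gradual dependent-to-nondependent decrease
  at baseline (about 3:1), and a redistribution toward dependent regions with
  near-zero nondependent perfusion after injury;
* a configurable coupling between normalized blood volume F_bn and normalized
  perfusion Q_n — linear at baseline, quadratic through the origin at injury —
  with larger residual scatter at baseline than injury;
* FDG time-activity curves following the Sokoloff three-compartment model
  driven by a 60-s constant-rate infusion input function, and ¹³NN breathhold
  curves with an early shunt peak decaying to a perfusion plateau.

The blood-fraction field is constructed *through* the normalization algebra:
the coupling model is applied in normalized (F_bn, Q_n) space and inverted to
absolute F_b, so that running the downstream pipeline on a noiseless bundle
returns exactly the intended normalized cloud. Because the normalization
constrains the tissue-weighted mean of F_bn to 1, an arbitrary coupling model
is first projected onto that constraint by a scalar rescaling; the achieved
(self-consistent) coefficients are recorded on the phantom as
``intended_coupling`` alongside the configured ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .coupling_stats import MODEL_FORMS
from .kinetics import InputFunction, TimeActivityCurve, SokoloffParams, sokoloff_forward

__all__ = [
    "CouplingModel",
    "PhantomConfig",
    "LungPhantom",
    "StudyBundle",
    "build_phantom",
    "make_input_function",
    "simulate_fdg_tac",
    "simulate_nn13_tac",
    "simulate_study",
    "sample_coupling_cloud",
    "write_bundle",
    "read_bundle",
    "default_fdg_frames",
    "default_nn13_frames",
]

CONDITIONS = ("baseline", "injury")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CouplingModel:
    """A polynomial F_bn = g(Q_n) coupling (a form from the model zoo)."""

    form: str
    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.form not in ("y=ax", "y=a+bx", "y=ax+bx^2", "y=a+bx+cx^2"):
            raise ValueError("phantom coupling must be a polynomial form")
        if len(self.coefficients) != MODEL_FORMS[self.form].k:
            raise ValueError("coefficient count does not match form")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return MODEL_FORMS[self.form].predict(np.asarray(self.coefficients),
                                              np.asarray(x, dtype=float))

    def scaled(self, s: float) -> "CouplingModel":
        """Coupling rescaled by 1/s (polynomial forms are linear in coefficients)."""
        return CouplingModel(self.form, tuple(c / s for c in self.coefficients))


def default_fdg_frames() -> tuple[np.ndarray, np.ndarray]:
    """6 x 10 s, 8 x 30 s, 10 x 60 s (14 min total)."""
    dur = np.array([10.0] * 6 + [30.0] * 8 + [60.0] * 10)
    end = np.cumsum(dur)
    return end - dur, end


def default_nn13_frames() -> tuple[np.ndarray, np.ndarray]:
    """30 x 2 s over the 60-s breathhold."""
    end = np.arange(2.0, 62.0, 2.0)
    return end - 2.0, end


@dataclass(frozen=True)
class PhantomConfig:
    """Study-design parameters of the synthetic generator.

    Defaults state the emulated study: 5 animals, 15 vertical layers x 2
    axial sections, the published baseline/injury coupling models with
    residual sd 0.15 / 0.08, cardiac output 4.8 +- 0.7 (baseline) and
    3.7 +- 1.1 l/min (injury), and pseudo-Poisson TAC noise with a lower
    FDG scale at injury (higher injected dose).
    """

    n_animals: int = 5
    n_layers: int = 15
    n_axial: int = 2
    coupling_baseline: CouplingModel = CouplingModel("y=a+bx", (0.32, 0.690))
    coupling_injury: CouplingModel = CouplingModel("y=ax+bx^2", (1.684, -0.538))
    residual_sd_baseline: float = 0.15
    residual_sd_injury: float = 0.08
    # vertical perfusion profiles, by condition
    perfusion_gradient: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "baseline": {"kind": "affine", "q_dependent": 1.5, "q_nondependent": 0.5},
            "injury": {"kind": "sigmoid", "h_mid": 0.5, "width": 0.21},
        })
    # F_gas = a + b*h, by condition
    gas_fraction_profile: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"baseline": (0.45, 0.25), "injury": (0.25, 0.40)})
    cardiac_output: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"baseline": (4.8, 0.7), "injury": (3.7, 1.1)})
    mean_blood_fraction: float = 0.15
    tac_noise_model: Mapping[str, float] = field(
        default_factory=lambda: {"fdg_scale_baseline": 0.08, "fdg_scale_injury": 0.035,
                                 "nn13_scale": 0.04, "floor": 0.05})
    input_function_params: Mapping[str, float] = field(
        default_factory=lambda: {"amplitude_baseline": 20.0, "amplitude_injury": 100.0,
                                 "infusion_s": 60.0, "alpha": 1.0 / 30.0,
                                 "beta": 1.0 / 600.0, "w_fast": 0.6})
    sokoloff_truth: Mapping[str, float] = field(
        default_factory=lambda: {"K1": 0.005, "k2": 0.05, "k3": 0.01, "jitter_sd": 0.2})
    shunt_params: Mapping[str, float] = field(
        default_factory=lambda: {"height_threshold": 0.7, "lo": 0.15, "hi": 0.45})
    axial_offset: float = 0.10          # relative perfusion offset between sections
    q_jitter_sd: float = 0.15           # lognormal per-ROI perfusion heterogeneity
    gas_jitter_sd: float = 0.01
    roi_volume_ml: float = 40.0
    volume_jitter_sd: float = 0.05
    nn13_activity_per_flow: float = 0.01   # kBq/ml per ml/min, arbitrary calibration
    missing_co_animal: bool = True      # one animal lacks injury cardiac output
    max_coupling_retries: int = 50
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_animals, self.n_layers, self.n_axial) < 1:
            raise ValueError("counts must be positive")
        if not self.residual_sd_baseline > self.residual_sd_injury:
            raise ValueError("residual_sd_baseline must exceed residual_sd_injury")
        if not 0 < self.mean_blood_fraction < 0.5:
            raise ValueError("mean_blood_fraction must be in (0, 0.5)")
        for cond in CONDITIONS:
            a, b = self.gas_fraction_profile[cond]
            for h in (0.0, 1.0):
                if not 0.0 <= a + b * h <= 1.0:
                    raise ValueError("gas-fraction profile leaves [0, 1]")

    def coupling(self, condition: str) -> CouplingModel:
        return self.coupling_baseline if condition == "baseline" else self.coupling_injury

    def residual_sd(self, condition: str) -> float:
        return (self.residual_sd_baseline if condition == "baseline"
                else self.residual_sd_injury)


def _check_condition(condition: str) -> None:
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")


def _rng(config: PhantomConfig, *stream: int) -> np.random.Generator:
    """Independent deterministic stream keyed on the config seed."""
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *stream])


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LungPhantom:
    """Ground-truth ROI maps of one animal under one condition."""

    condition: str
    animal_id: int
    roi: pd.DataFrame               # one row per ROI, truth columns
    cardiac_output: float           # l/min
    intended_coupling: CouplingModel
    configured_coupling: CouplingModel
    coupling_scale: float           # configured / intended scalar

    def __post_init__(self) -> None:
        r = self.roi
        if np.any(r["F_gas_true"] + r["F_b_true"] > 1 + 1e-12):
            raise ValueError("F_gas + F_b exceeds 1")
        if np.any(r["Q_r_true"] < 0):
            raise ValueError("negative perfusion")

    @property
    def n_rois(self) -> int:
        return len(self.roi)


def _vertical_profile(cfg: PhantomConfig, condition: str, h: np.ndarray) -> np.ndarray:
    p = cfg.perfusion_gradient[condition]
    if p["kind"] == "affine":
        return p["q_dependent"] + (p["q_nondependent"] - p["q_dependent"]) * h
    if p["kind"] == "sigmoid":
        return 1.0 / (1.0 + np.exp((h - p["h_mid"]) / p["width"]))
    raise ValueError(f"unknown profile kind {p['kind']!r}")


def build_phantom(config: PhantomConfig, animal_id: int, condition: str) -> LungPhantom:
    """Construct ground truth for one animal-condition.

    Perfusion follows the condition's vertical profile with per-ROI
    heterogeneity and a mild inter-section offset. F_b is obtained by a fixed
    point of the normalization algebra so the intended (Q_n, F_bn) cloud is
    exactly what the downstream pipeline recovers on noiseless data.
    """
    config.validate()
    _check_condition(condition)
    cond_code = CONDITIONS.index(condition)
    n_layers, n_axial = config.n_layers, config.n_axial
    n_roi = n_layers * n_axial

    layer = np.repeat(np.arange(1, n_layers + 1), n_axial)
    section = np.tile(np.arange(1, n_axial + 1), n_layers)
    h = (layer - 0.5) / n_layers          # 0 = most dependent (dorsal, supine)

    rng = _rng(config, animal_id, cond_code, 0)
    q = _vertical_profile(config, condition, h)
    if n_axial > 1:
        q = q * (1.0 + config.axial_offset * (section - (n_axial + 1) / 2.0)
                 / ((n_axial - 1) / 2.0) / 2.0)
    q = q * np.exp(rng.normal(0.0, config.q_jitter_sd, n_roi))

    co_mean, co_sd = config.cardiac_output[condition]
    co = float(np.clip(rng.normal(co_mean, co_sd), 0.3 * co_mean, None))

    a_g, b_g = config.gas_fraction_profile[condition]
    F_gas = np.clip(a_g + b_g * h + rng.normal(0.0, config.gas_jitter_sd, n_roi),
                    0.02, 0.92)

    # --- invert the coupling through the normalization algebra -------------
    # The vertical profile q defines *normalized* perfusion; Q_n is q scaled
    # so that mean(Q_n * F_tis_n) = 1, and both Q_r and F_b are then
    # back-transformed so the downstream normalization recovers the intended
    # (Q_n, F_bn) cloud exactly.
    g = config.coupling(condition)
    sd = config.residual_sd(condition)
    m_b = config.mean_blood_fraction
    eps = rng.normal(0.0, sd, n_roi) if sd > 0 else np.zeros(n_roi)

    F_b = np.full(n_roi, m_b)
    scale = 1.0
    for attempt in range(config.max_coupling_retries + 1):
        for _ in range(400):
            F_tis = 1.0 - F_gas - F_b
            w = F_tis / F_tis.mean()
            Q_n = q / np.mean(q * w)
            y = g(Q_n) + eps
            s = float(np.mean(y * w))
            if s <= 0:
                raise RuntimeError(
                    f"coupling model yields a nonpositive tissue-weighted mean "
                    f"F_bn for animal {animal_id} {condition}: the configured "
                    f"coupling produces F_b outside (0, 1-F_gas)")
            y = y / s
            F_b_raw = m_b * y * w
            # clamp inside the loop so F_tis stays positive; infeasible
            # residual draws are detected from the unclamped values below
            F_b_new = np.clip(F_b_raw, 1e-4, 1.0 - F_gas - 1e-4)
            if np.max(np.abs(F_b_new - F_b)) < 1e-14:
                F_b = F_b_new
                break
            F_b = F_b_new
        bad = ((F_b_raw <= 1e-4) | (F_b_raw >= 1.0 - F_gas - 1e-4)
               | ~np.isfinite(F_b_raw))
        if not np.any(bad):
            scale = s
            break
        if sd == 0 or attempt == config.max_coupling_retries:
            raise RuntimeError(
                f"coupling model yields F_b outside (0, 1-F_gas) for animal "
                f"{animal_id} {condition}: ROIs {np.where(bad)[0].tolist()}")
        eps[bad] = rng.normal(0.0, sd, int(bad.sum()))
        F_b = np.where(bad, m_b, F_b)

    F_tis = 1.0 - F_gas - F_b
    w = F_tis / F_tis.mean()
    Q_n_int = q / np.mean(q * w)
    q_raw = Q_n_int * w
    Q_r = q_raw / q_raw.sum() * co * 1000.0   # ml/min, summing to cardiac output
    F_bn_int = (F_b / F_b.mean()) / w

    shunt = np.zeros(n_roi)
    if condition == "injury":
        sp = config.shunt_params
        nondep = h > sp["height_threshold"]
        shunt[nondep] = rng.uniform(sp["lo"], sp["hi"], int(nondep.sum()))

    st = config.sokoloff_truth
    jit = st["jitter_sd"]
    K1 = st["K1"] * np.exp(rng.normal(0.0, jit, n_roi))
    k2 = st["k2"] * np.exp(rng.normal(0.0, jit, n_roi))
    k3 = st["k3"] * np.exp(rng.normal(0.0, jit, n_roi))

    vol = config.roi_volume_ml * np.exp(rng.normal(0.0, config.volume_jitter_sd, n_roi))

    roi = pd.DataFrame({
        "roi_id": [f"L{l:02d}S{s}" for l, s in zip(layer, section)],
        "layer_index": layer,
        "axial_section": section,
        "height_fraction": h,
        "F_gas_true": F_gas,
        "F_b_true": F_b,
        "Q_r_true": Q_r,
        "shunt_fraction_true": shunt,
        "roi_volume": vol,
        "K1_true": K1,
        "k2_true": k2,
        "k3_true": k3,
        "Q_n_intended": Q_n_int,
        "F_bn_intended": F_bn_int,
    })
    return LungPhantom(condition=condition, animal_id=animal_id, roi=roi,
                       cardiac_output=co, intended_coupling=g.scaled(scale),
                       configured_coupling=g, coupling_scale=scale)


# ---------------------------------------------------------------------------
# tracer simulation
# ---------------------------------------------------------------------------

def make_input_function(kind: str, params: Mapping[str, float],
                        times: np.ndarray) -> InputFunction:
    """Plasma input function C_p(t) for a 60-s constant-rate infusion.

    Linear rise over the infusion, then a two-exponential decay; C_p(0) = 0
    and C_p scales linearly with the ``amplitude`` parameter.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if abs(times[0]) > 1e-12:
        raise ValueError("times must start at 0")
    if kind != "infusion":
        raise ValueError(f"unknown input-function kind {kind!r}")
    A = float(params.get("amplitude", 1.0))
    T = float(params.get("infusion_s", 60.0))
    alpha = float(params.get("alpha", 1.0 / 30.0))
    beta = float(params.get("beta", 1.0 / 600.0))
    wf = float(params.get("w_fast", 0.6))
    rising = times <= T
    cp = np.where(rising, A * times / T,
                  A * (wf * np.exp(-alpha * np.maximum(times - T, 0.0))
                       + (1.0 - wf) * np.exp(-beta * np.maximum(times - T, 0.0))))
    return InputFunction(times, cp)


def _tac_noise_sd(activity: np.ndarray, scale: float, floor: float) -> np.ndarray:
    # pseudo-Poisson: sd grows with sqrt(signal), with an additive floor
    return scale * (np.sqrt(np.maximum(activity, 0.0)) + floor)


def simulate_fdg_tac(roi_row: Mapping, input_function: InputFunction,
                     frame_start: np.ndarray, frame_end: np.ndarray,
                     noise_scale: float = 0.0, floor: float = 0.05,
                     rng: np.random.Generator | None = None) -> TimeActivityCurve:
    """FDG TAC of one phantom ROI: Sokoloff forward model plus frame noise."""
    if float(np.max(frame_end)) - float(np.min(frame_start)) < 600.0:
        raise ValueError("FDG frames must cover at least 10 min")
    params = SokoloffParams(float(roi_row["F_b_true"]), float(roi_row["K1_true"]),
                            float(roi_row["k2_true"]), float(roi_row["k3_true"]))
    tac = sokoloff_forward(params, input_function, frame_start, frame_end)
    act = tac.activity
    if noise_scale > 0:
        if rng is None:
            raise ValueError("rng required when noise is on")
        act = act + rng.normal(0.0, 1.0, act.size) * _tac_noise_sd(act, noise_scale, floor)
    return TimeActivityCurve(tac.frame_start, tac.frame_end, act, tracer="FDG")


_PULSE_TP = 8.0  # s, time of the early shunt peak


def _shunt_pulse(t: np.ndarray) -> np.ndarray:
    """Gamma-variate transient: unit peak at t = _PULSE_TP, ~0 beyond 40 s."""
    tau = np.maximum(t, 0.0) / _PULSE_TP
    return tau**2 * np.exp(2.0 * (1.0 - tau))


def simulate_nn13_tac(roi_row: Mapping, frame_start: np.ndarray,
                      frame_end: np.ndarray, activity_per_flow: float = 0.01,
                      noise_scale: float = 0.0, floor: float = 0.05,
                      rng: np.random.Generator | None = None) -> TimeActivityCurve:
    """¹³NN breathhold TAC: perfusion plateau plus an early shunt peak.

    The plateau is proportional to aerated perfusion ``Q_r*(1-shunt)``; with a
    nonzero shunt fraction the curve carries an early transient whose maximum
    frame value equals ``Q_r`` (in activity units), so plateau + peak excess
    recovers total regional perfusion by construction.
    """
    fs = np.asarray(frame_start, dtype=float)
    fe = np.asarray(frame_end, dtype=float)
    if fe[-1] - fs[0] < 45.0:
        raise ValueError("¹³NN frames must span the 60-s breathhold")
    Q = float(roi_row["Q_r_true"]) * activity_per_flow
    s = float(roi_row["shunt_fraction_true"])
    plateau = Q * (1.0 - s)
    mid = 0.5 * (fs + fe)
    if s > 0:
        pulse = _shunt_pulse(mid)
        pulse = pulse / pulse.max()       # peak frame hits Q exactly
        act = plateau + (Q - plateau) * pulse
    else:
        act = np.full(mid.size, plateau)
    if noise_scale > 0:
        if rng is None:
            raise ValueError("rng required when noise is on")
        act = act + rng.normal(0.0, 1.0, act.size) * _tac_noise_sd(act, noise_scale, floor)
    return TimeActivityCurve(fs, fe, act, tracer="NN13")


# ---------------------------------------------------------------------------
# whole-study simulation
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """Everything a downstream analysis needs for one synthetic study."""

    config: PhantomConfig
    phantoms: dict[tuple[int, str], LungPhantom]
    input_functions: dict[tuple[int, str], InputFunction]
    fdg_tacs: dict[tuple[int, str], dict[str, TimeActivityCurve]]
    nn13_tacs: dict[tuple[int, str], dict[str, TimeActivityCurve]]
    hemodynamics: pd.DataFrame          # animal, CO_BL, CO_INJ (NaN if missing)

    @property
    def animals(self) -> list[int]:
        return sorted({a for a, _ in self.phantoms})


def simulate_study(config: PhantomConfig, noiseless: bool = False) -> StudyBundle:
    """Simulate the full study: all animals, both conditions, both tracers.

    ``noiseless=True`` switches off TAC noise (the coupling residual is
    governed separately by the residual-sd fields), which together with
    zero residual sds gives the fully deterministic closed-loop bundle.
    """
    config.validate()
    phantoms: dict[tuple[int, str], LungPhantom] = {}
    input_functions: dict[tuple[int, str], InputFunction] = {}
    fdg: dict[tuple[int, str], dict[str, TimeActivityCurve]] = {}
    nn13: dict[tuple[int, str], dict[str, TimeActivityCurve]] = {}
    rows = []
    fdg_fs, fdg_fe = default_fdg_frames()
    nn_fs, nn_fe = default_nn13_frames()
    if_times = np.arange(0.0, float(fdg_fe[-1]) + 61.0, 1.0)
    nm = config.tac_noise_model

    for animal in range(1, config.n_animals + 1):
        row = {"animal": animal}
        for condition in CONDITIONS:
            cond_code = CONDITIONS.index(condition)
            ph = build_phantom(config, animal, condition)
            phantoms[(animal, condition)] = ph
            amp = config.input_function_params[
                "amplitude_baseline" if condition == "baseline" else "amplitude_injury"]
            inp = make_input_function(
                "infusion", {**config.input_function_params, "amplitude": amp}, if_times)
            input_functions[(animal, condition)] = inp

            fdg_scale = 0.0 if noiseless else nm[
                "fdg_scale_baseline" if condition == "baseline" else "fdg_scale_injury"]
            nn_scale = 0.0 if noiseless else nm["nn13_scale"]
            rng_t = _rng(config, animal, cond_code, 1)
            fdg[(animal, condition)] = {
                r["roi_id"]: simulate_fdg_tac(r, inp, fdg_fs, fdg_fe,
                                              fdg_scale, nm["floor"], rng_t)
                for _, r in ph.roi.iterrows()}
            nn13[(animal, condition)] = {
                r["roi_id"]: simulate_nn13_tac(r, nn_fs, nn_fe,
                                               config.nn13_activity_per_flow,
                                               nn_scale, nm["floor"], rng_t)
                for _, r in ph.roi.iterrows()}
            key = "CO_BL" if condition == "baseline" else "CO_INJ"
            row[key] = ph.cardiac_output
        rows.append(row)

    hemo = pd.DataFrame(rows)
    if config.missing_co_animal and config.n_animals >= 1:
        # the last animal's injury cardiac output is unreliable -> missing
        hemo.loc[hemo.index[-1], "CO_INJ"] = np.nan
    return StudyBundle(config, phantoms, input_functions, fdg, nn13, hemo)


def sample_coupling_cloud(config: PhantomConfig, condition: str,
                          rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw one pooled (Q_n, F_bn) cloud directly in coupling space.

    Per animal: Q_n from the condition's vertical profile (with per-ROI
    heterogeneity and the inter-section offset) normalized to mean 1, and
    F_bn from the coupling model plus Gaussian residual. No kinetics and no
    tissue-fraction algebra are involved; this sampler expresses the
    condition's coupling hypothesis alone.
    """
    config.validate()
    _check_condition(condition)
    g = config.coupling(condition)
    sd = config.residual_sd(condition)
    n_roi = config.n_layers * config.n_axial
    layer = np.repeat(np.arange(1, config.n_layers + 1), config.n_axial)
    section = np.tile(np.arange(1, config.n_axial + 1), config.n_layers)
    h = (layer - 0.5) / config.n_layers
    xs, ys = [], []
    for _ in range(config.n_animals):
        q = _vertical_profile(config, condition, h)
        if config.n_axial > 1:
            q = q * (1.0 + config.axial_offset * (section - (config.n_axial + 1) / 2.0)
                     / ((config.n_axial - 1) / 2.0) / 2.0)
        q = q * np.exp(rng.normal(0.0, config.q_jitter_sd, n_roi))
        Q_n = q / q.mean()
        F_bn = g(Q_n) + (rng.normal(0.0, sd, n_roi) if sd > 0 else 0.0)
        xs.append(Q_n)
        ys.append(F_bn)
    return np.concatenate(xs), np.concatenate(ys)


# ---------------------------------------------------------------------------
# bundle I/O
# ---------------------------------------------------------------------------

def _tac_frame(tacs: dict, tracer: str) -> pd.DataFrame:
    recs = []
    for (animal, condition), d in sorted(tacs.items()):
        for roi_id, tac in d.items():
            for s, e, a in zip(tac.frame_start, tac.frame_end, tac.activity):
                recs.append((animal, condition, roi_id, tracer, s, e, a))
    return pd.DataFrame(recs, columns=["animal", "condition", "roi_id", "tracer",
                                       "frame_start_s", "frame_end_s", "activity"])


def write_bundle(bundle: StudyBundle, out_dir: str | Path) -> Path:
    """Persist a StudyBundle as a directory of plain-text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = pd.concat(
        [ph.roi.assign(animal=a, condition=c,
                       cardiac_output=ph.cardiac_output,
                       coupling_scale=ph.coupling_scale)
         for (a, c), ph in sorted(bundle.phantoms.items())],
        ignore_index=True)
    truth.to_csv(out / "roi_truth.csv", index=False)

    pd.concat([_tac_frame(bundle.fdg_tacs, "FDG"),
               _tac_frame(bundle.nn13_tacs, "NN13")],
              ignore_index=True).to_csv(out / "tacs.csv", index=False)

    recs = []
    for (animal, condition), inp in sorted(bundle.input_functions.items()):
        for t, c in zip(inp.times, inp.Cp):
            recs.append((animal, condition, t, c))
    pd.DataFrame(recs, columns=["animal", "condition", "time_s", "Cp"]
                 ).to_csv(out / "input_functions.csv", index=False)

    bundle.hemodynamics.to_csv(out / "hemodynamics.csv", index=False)

    cfg = dataclasses.asdict(bundle.config)
    cfg["coupling_baseline"] = {"form": bundle.config.coupling_baseline.form,
                                "coefficients": list(bundle.config.coupling_baseline.coefficients)}
    cfg["coupling_injury"] = {"form": bundle.config.coupling_injury.form,
                              "coefficients": list(bundle.config.coupling_injury.coefficients)}
    manifest = {
        "config": _plainify(cfg),
        "n_animals": bundle.config.n_animals,
        "n_rois_per_condition": bundle.config.n_animals
        * bundle.config.n_layers * bundle.config.n_axial,
        "files": ["roi_truth.csv", "tacs.csv", "input_functions.csv", "hemodynamics.csv"],
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return out


def write_phantom_maps(phantom: LungPhantom, out_dir: str | Path,
                       shape: tuple[int, int, int] = (45, 20, 16)) -> Path:
    """Optional volumetric view of a phantom: a cuboid lung mask partitioned
    into the phantom's ROIs with per-voxel truth maps (NIfTI)."""
    import nibabel as nib
    from .regional import partition_rois

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_layers = int(phantom.roi["layer_index"].max())
    n_axial = int(phantom.roi["axial_section"].max())
    mask = np.ones(shape, dtype=bool)
    labels = partition_rois(mask, n_layers=n_layers, n_axial=n_axial)
    aff = np.eye(4)
    nib.save(nib.Nifti1Image(labels, aff), str(out / "roi_labels.nii.gz"))
    by_label = phantom.roi.sort_values(["layer_index", "axial_section"])
    for col in ("F_gas_true", "F_b_true", "Q_r_true"):
        lut = np.concatenate([[0.0], by_label[col].to_numpy()])
        vol = lut[labels]
        nib.save(nib.Nifti1Image(vol.astype(np.float32), aff),
                 str(out / f"{col}.nii.gz"))
    return out


def _plainify(obj):
    if isinstance(obj, Mapping):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_from_dict(d: Mapping) -> PhantomConfig:
    d = dict(d)
    for key in ("coupling_baseline", "coupling_injury"):
        if key in d and isinstance(d[key], Mapping):
            d[key] = CouplingModel(d[key]["form"], tuple(d[key]["coefficients"]))
    known = {f.name for f in dataclasses.fields(PhantomConfig)}
    return PhantomConfig(**{k: v for k, v in d.items() if k in known})


def read_bundle(in_dir: str | Path) -> StudyBundle:
    """Reload a bundle written by :func:`write_bundle` (regenerates phantoms
    deterministically from the stored config and checks the stored truth)."""
    src = Path(in_dir)
    manifest = yaml.safe_load((src / "manifest.yaml").read_text())
    config = config_from_dict(manifest["config"])

    truth = pd.read_csv(src / "roi_truth.csv")
    tacs = pd.read_csv(src / "tacs.csv")
    inpf = pd.read_csv(src / "input_functions.csv")
    hemo = pd.read_csv(src / "hemodynamics.csv")

    phantoms, input_functions, fdg, nn13 = {}, {}, {}, {}
    for (animal, condition), grp in truth.groupby(["animal", "condition"]):
        ph = build_phantom(config, int(animal), str(condition))
        if not np.allclose(grp["F_b_true"].to_numpy(), ph.roi["F_b_true"].to_numpy()):
            raise ValueError("bundle truth does not match its config/seed")
        phantoms[(int(animal), str(condition))] = ph
    for (animal, condition), grp in inpf.groupby(["animal", "condition"]):
        input_functions[(int(animal), str(condition))] = InputFunction(
            grp["time_s"].to_numpy(), grp["Cp"].to_numpy())
    for (animal, condition, tracer), grp in tacs.groupby(["animal", "condition", "tracer"]):
        store = fdg if tracer == "FDG" else nn13
        d = store.setdefault((int(animal), str(condition)), {})
        for roi_id, g2 in grp.groupby("roi_id"):
            g2 = g2.sort_values("frame_start_s")
            d[str(roi_id)] = TimeActivityCurve(
                g2["frame_start_s"].to_numpy(), g2["frame_end_s"].to_numpy(),
                g2["activity"].to_numpy(), tracer=str(tracer))
    return StudyBundle(config, phantoms, input_functions, fdg, nn13, hemo)
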