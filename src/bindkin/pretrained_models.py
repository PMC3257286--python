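"""The four published rate-constant model pairs, ready to evaluate.

Models a-d are the best-performing (k_on, k_off) pairs from the original
study of the protein-protein kinetics benchmark, transcribed with their
intercepts ("CONSTANT"), absolute weights (response units per descriptor
unit), normalized (z-score) weights, and training RMS / LOO-CV RMSE.
They differ in how the benchmark was partitioned and which surface
criterion picked them:

    a - high-confidence-only training, selected by RMSE, outlier kept
    b - full kinetic training set, selected by RMSE, outlier kept
    c - full kinetic training set, selected by RMSE, 2oza omitted
    d - full kinetic training set, selected by correlation, 2oza omitted

The coefficients are transcribed constants, not refits: the exact
training rows behind each fit are not recoverable, so refitting is a
separate workflow (`bindkin.workflow`).  Descriptor symbols are the
field's: NUM_HB (interfacial H-bond count), DFIRE_EBU (ensemble-averaged
bound-vs-unbound conformational energy under the DFIRE potential),
ROS_CG_BETA / ROS_CG_VDW (PyRosetta coarse-grain potentials), OPUS_CA_ENS,
NIP (interface packing), RES_C (charged interface-residue fraction),
STC_H (binding enthalpy score), GEN_4_BODY_UB, S_WLC_INT2 (disorder-to-
order entropy), MJ2H_PP and MJPL_PP_UB (residue contact potentials).
"""

from __future__ import annotations

from typing import Mapping

from .regression import LinearRateModel
from .thermo import DEFAULT_CONTEXT, ThermoContext, dg_from_log_rates

MODEL_IDS = ("a", "b", "c", "d")

_KON_CD = LinearRateModel(
    target="log10_kon",
    features=("RES_C", "NUM_HB", "ROS_CG_VDW", "STC_H", "GEN_4_BODY_UB",
              "DFIRE_EBU", "S_WLC_INT2"),
    intercept=5.80,
    weights=(-6.87e-2, 7.99e-2, -1.01, -5.84e-2, 1.43e-2, -2.76e-3, -2.77e-1),
    normalized_weights=(-0.53, 0.42, -0.27, -0.28, 0.39, -0.41, -0.19),
    metrics={"rms": 0.76, "cv_rmse": 0.90},
)

REGISTRY: dict[str, tuple[LinearRateModel, LinearRateModel]] = {
    "a": (
        LinearRateModel(
            target="log10_kon",
            features=("NUM_HB", "DFIRE_EBU"),
            intercept=4.29,
            weights=(7.29e-2, -3.60e-3),
            normalized_weights=(0.52, -0.50),
            metrics={"rms": 0.81, "cv_rmse": 0.89},
        ),
        LinearRateModel(
            target="log10_koff",
            features=("ROS_CG_BETA", "OPUS_CA_ENS"),
            intercept=-2.11,
            weights=(-6.77e-1, 3.77e-2),
            normalized_weights=(-0.73, 0.67),
            metrics={"rms": 1.41, "cv_rmse": 1.58},
        ),
    ),
    "b": (
        LinearRateModel(
            target="log10_kon",
            features=("NUM_HB", "DFIRE_EBU"),
            intercept=4.18,
            weights=(7.09e-2, -3.19e-3),
            normalized_weights=(0.39, -0.47),
            metrics={"rms": 1.05, "cv_rmse": 1.14},
        ),
        LinearRateModel(
            target="log10_koff",
            features=("ROS_CG_BETA", "NIP"),
            intercept=-6.32,
            weights=(-4.89e-1, 8.61e3),
            normalized_weights=(-0.52, 0.51),
            metrics={"rms": 1.39, "cv_rmse": 1.47},
        ),
    ),
    "c": (
        _KON_CD,
        LinearRateModel(
            target="log10_koff",
            features=("MJ2H_PP",),
            intercept=-0.87,
            weights=(1.20e-2,),
            normalized_weights=(0.46,),
            metrics={"rms": 1.44, "cv_rmse": 1.52},
        ),
    ),
    "d": (
        _KON_CD,
        LinearRateModel(
            target="log10_koff",
            features=("MJ2H_PP", "MJPL_PP_UB"),
            intercept=-0.67,
            weights=(1.36e-2, 3.98e-3),
            normalized_weights=(0.53, 0.40),
            metrics={"rms": 1.29, "cv_rmse": 1.43},
        ),
    ),
}


def get_models(model_id: str) -> tuple[LinearRateModel, LinearRateModel]:
    """(k_on model, k_off model) for one of the published models a-d."""
    try:
        return REGISTRY[model_id]
    except KeyError:
        raise KeyError(f"model_id must be one of {MODEL_IDS}, "
                       f"got {model_id!r}") from None


def required_descriptors(model_id: str) -> tuple[str, ...]:
    """Union of descriptor names needed by both halves of a model pair."""
    kon, koff = get_models(model_id)
    seen: list[str] = []
    for f in (*kon.features, *koff.features):
        if f not in seen:
            seen.append(f)
    return tuple(seen)


def _evaluate(model: LinearRateModel, descriptors: Mapping[str, float]) -> float:
    missing = [f for f in model.features if f not in descriptors]
    if missing:
        raise KeyError(
            f"missing descriptors {missing}; required: {list(model.features)}"
        )
    x = [float(descriptors[f]) for f in model.features]
    return float(model.predict([x])[0])


def predict(model_id: str, target: str, descriptors: Mapping[str, float]) -> float:
    """log10 k_on or log10 k_off from one published model."""
    kon, koff = get_models(model_id)
    if target == "log10_kon":
        return _evaluate(kon, descriptors)
    if target == "log10_koff":
        return _evaluate(koff, descriptors)
    raise ValueError(f"target must be 'log10_kon' or 'log10_koff', got {target!r}")


def predict_binding(
    model_id: str,
    descriptors: Mapping[str, float],
    ctx: ThermoContext = DEFAULT_CONTEXT,
) -> dict[str, float]:
    """Consistent {log10_kon, log10_koff, log10_Kd, dg} bundle.

    dg (kcal/mol) follows ΔG = ln(10)·RT·(log10 k_off − log10 k_on), and
    log10_Kd = log10_koff − log10_kon exactly.
    """
    log_kon = predict(model_id, "log10_kon", descriptors)
    log_koff = predict(model_id, "log10_koff", descriptors)
    return {
        "log10_kon": log_kon,
        "log10_koff": log_koff,
        "log10_Kd": log_koff - log_kon,
        "dg": dg_from_log_rates(log_kon, log_koff, ctx),
    }
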