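"""Time–activity curves and multi-exponential biokinetic models.

A region's washout is modelled as a sum of 1–3 decaying exponentials.
Two representations exist for the same kinetics:

* ``biological_q`` — decay-corrected ("q" curves): rates are the
  biological clearance constants λB of the unlabelled compound.
* ``effective_A`` — as-measured ("A" curves) for the radiolabelled
  compound: each rate is λeff = λB + λR, with λR the physical decay
  constant of the label.

``to_effective``/``to_biological`` convert between the two by shifting
every rate by λR; coefficients are untouched. Fitting happens in the
representation the data were recorded in, so the noise structure is
preserved (raw data are never pre-multiplied by exp(λR·t)).
"""

from __future__ import annotations

import json
import math
from enum import Enum
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .estimator import FitConvergenceError, MultiExponentialDecay
from .nuclide import LN2, Radionuclide

__all__ = [
    "Representation",
    "TimeActivitySample",
    "TimeActivityCurve",
    "ExponentialTerm",
    "BiokineticModel",
    "fit_model",
    "to_effective",
    "to_biological",
    "evaluate",
    "phase_half_lives",
    "round_sig",
    "FitConvergenceError",
]


class Representation(str, Enum):
    biological_q = "biological_q"
    effective_A = "effective_A"


class TimeActivitySample(BaseModel):
    """One biodistribution measurement: %IA in a region at a time point."""

    model_config = ConfigDict(extra="forbid")

    time_h: float = Field(ge=0)
    value_pct_ia: float = Field(ge=0)
    n_animals: int | None = Field(default=None, ge=1)
    sd_pct_ia: float | None = Field(default=None, ge=0)
    decay_corrected: bool = False


class TimeActivityCurve(BaseModel):
    """Ordered time–activity samples for one region.

    Sample times must be strictly increasing and all samples must share
    the same ``decay_corrected`` flag (one representation per curve).
    """

    model_config = ConfigDict(extra="forbid")

    region: str
    samples: list[TimeActivitySample]

    @model_validator(mode="after")
    def _check(self) -> "TimeActivityCurve":
        times = [s.time_h for s in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample times must be strictly increasing")
        flags = {s.decay_corrected for s in self.samples}
        if len(flags) > 1:
            raise ValueError("all samples in a curve must share decay_corrected")
        return self

    @property
    def decay_corrected(self) -> bool:
        return bool(self.samples and self.samples[0].decay_corrected)

    @property
    def times_h(self) -> np.ndarray:
        return np.array([s.time_h for s in self.samples])

    @property
    def values_pct_ia(self) -> np.ndarray:
        return np.array([s.value_pct_ia for s in self.samples])


class ExponentialTerm(BaseModel):
    """One exponential phase: amplitude (%IA) and decay rate (h⁻¹)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    coefficient_pct_ia: float = Field(ge=0)
    rate_per_h: float = Field(gt=0)


class FitDiagnostics(BaseModel):
    model_config = ConfigDict(extra="forbid")

    rss: float
    aicc: float
    param_se: list[float] | None = None
    n_samples: int
    weighting: str = "none"


class BiokineticModel(BaseModel):
    """Sum-of-exponentials model for one region, in a stated representation.

    Terms are kept sorted by rate descending (fast phase first); the
    value at t = 0 is the sum of the coefficients.
    """

    model_config = ConfigDict(extra="forbid")

    region: str
    terms: list[ExponentialTerm] = Field(min_length=1, max_length=3)
    representation: Representation
    nuclide: Radionuclide
    fit_diagnostics: FitDiagnostics | None = None

    @model_validator(mode="after")
    def _sort_terms(self) -> "BiokineticModel":
        self.terms = sorted(self.terms, key=lambda tm: tm.rate_per_h, reverse=True)
        return self

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([tm.coefficient_pct_ia for tm in self.terms])

    @property
    def rates(self) -> np.ndarray:
        return np.array([tm.rate_per_h for tm in self.terms])

    # -- serialization -------------------------------------------------
    def to_json_dict(self) -> dict:
        out = {
            "region": self.region,
            "representation": self.representation.value,
            "nuclide": {"name": self.nuclide.name,
                        "half_life_h": self.nuclide.half_life_h},
            "terms": [
                {"coefficient_pct_ia": tm.coefficient_pct_ia,
                 "rate_per_h": tm.rate_per_h}
                for tm in self.terms
            ],
        }
        if self.fit_diagnostics is not None:
            out["diagnostics"] = self.fit_diagnostics.model_dump()
        return out

    @classmethod
    def from_json_dict(cls, data: dict) -> "BiokineticModel":
        diag = data.get("diagnostics")
        return cls(
            region=data["region"],
            representation=Representation(data["representation"]),
            nuclide=Radionuclide.model_validate(data["nuclide"]),
            terms=[ExponentialTerm.model_validate(t) for t in data["terms"]],
            fit_diagnostics=FitDiagnostics.model_validate(diag) if diag else None,
        )


# ----------------------------------------------------------------------
def fit_model(
    curve: TimeActivityCurve,
    nuclide: Radionuclide,
    n_terms: int | Literal["auto"] = 2,
    weighting: Literal["none", "inverse_variance"] = "none",
    random_state: int = 0,
) -> BiokineticModel:
    """Fit a 1–3 term exponential washout model to a time–activity curve.

    The model is fitted in the curve's own representation (q-domain for
    decay-corrected data, A-domain otherwise). With ``n_terms="auto"``
    the 1-, 2- and 3-term fits are compared by AICc and the minimum
    returned. Requires at least ``2·n_terms`` samples.
    """
    t, y = curve.times_h, curve.values_pct_ia
    sd = np.array([s.sd_pct_ia if s.sd_pct_ia is not None else np.nan
                   for s in curve.samples])
    sample_sd = sd if weighting == "inverse_variance" else None
    if sample_sd is not None and np.any(~np.isfinite(sd)):
        raise ValueError("inverse_variance weighting needs sd_pct_ia on every sample")

    if n_terms == "auto":
        candidates = []
        for k in (1, 2, 3):
            if len(t) < 2 * k:
                continue
            try:
                est = MultiExponentialDecay(
                    n_terms=k, weights=weighting, random_state=random_state
                ).fit(t, y, sample_sd=sample_sd)
            except FitConvergenceError:
                continue
            candidates.append(est)
        if not candidates:
            raise FitConvergenceError("no term count converged", {})
        est = min(candidates, key=lambda e: e.aicc_)
    else:
        est = MultiExponentialDecay(
            n_terms=int(n_terms), weights=weighting, random_state=random_state
        ).fit(t, y, sample_sd=sample_sd)

    rep = (Representation.biological_q if curve.decay_corrected
           else Representation.effective_A)
    terms = [
        ExponentialTerm(coefficient_pct_ia=float(c), rate_per_h=float(r))
        for c, r in zip(est.coefficients_, est.rates_)
    ]
    diag = FitDiagnostics(
        rss=est.rss_,
        aicc=est.aicc_,
        param_se=None if est.param_se_ is None else [float(v) for v in est.param_se_],
        n_samples=len(t),
        weighting=weighting,
    )
    return BiokineticModel(
        region=curve.region, terms=terms, representation=rep,
        nuclide=nuclide, fit_diagnostics=diag,
    )


def to_effective(model: BiokineticModel) -> BiokineticModel:
    """q → A: add λR to every rate. Errors if already effective."""
    if model.representation is not Representation.biological_q:
        raise ValueError(
            "model is already in effective_A representation; refusing to "
            "apply the decay constant twice"
        )
    lam_r = model.nuclide.decay_constant_per_h
    terms = [
        ExponentialTerm(coefficient_pct_ia=tm.coefficient_pct_ia,
                        rate_per_h=tm.rate_per_h + lam_r)
        for tm in model.terms
    ]
    return model.model_copy(update={
        "terms": terms, "representation": Representation.effective_A,
    })


def to_biological(model: BiokineticModel) -> BiokineticModel:
    """A → q: subtract λR from every rate (decay correction).

    Errors if any effective rate does not exceed λR — the biological
    clearance rate would be non-positive, i.e. the region retains the
    compound indefinitely, which the washout model cannot represent.
    """
    if model.representation is not Representation.effective_A:
        raise ValueError("model is already in biological_q representation")
    lam_r = model.nuclide.decay_constant_per_h
    bad = [tm.rate_per_h for tm in model.terms if tm.rate_per_h <= lam_r]
    if bad:
        raise ValueError(
            f"effective rates {bad} do not exceed λR = {lam_r} h⁻¹; "
            "biological rate would be non-positive"
        )
    terms = [
        ExponentialTerm(coefficient_pct_ia=tm.coefficient_pct_ia,
                        rate_per_h=tm.rate_per_h - lam_r)
        for tm in model.terms
    ]
    return model.model_copy(update={
        "terms": terms, "representation": Representation.biological_q,
    })


def evaluate(model: BiokineticModel, t: float | Sequence[float]) -> float | np.ndarray:
    """Model value Σ cᵢ·exp(−λᵢ t) in %IA at time(s) t ≥ 0 (hours)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be ≥ 0")
    vals = (model.coefficients[None, :]
            * np.exp(-np.outer(np.atleast_1d(t_arr), model.rates))).sum(axis=1)
    return float(vals[0]) if t_arr.ndim == 0 else vals


def phase_half_lives(model: BiokineticModel) -> list[float]:
    """Per-phase half-lives ln(2)/λᵢ in hours, fast phase first."""
    return [LN2 / tm.rate_per_h for tm in model.terms]


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (report-layer rounding)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def save_models_json(models: Sequence[BiokineticModel], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([m.to_json_dict() for m in models], indent=1) + "\n",
        encoding="utf-8",
    )


def load_models_json(path: str | Path) -> list[BiokineticModel]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return [BiokineticModel.from_json_dict(d) for d in data]
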