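"""Trivariate Gaussian diagnostic model and clinical threshold classifier.

The data-driven criterion models the normal-development cluster's angle
triplets x = (θCE, θsharp, θTönnis)ᵀ as a trivariate normal distribution

    p(x) = (2π)^(-3/2) |Σ|^(-1/2) exp(-½ (x-μ)ᵀ Σ⁻¹ (x-μ))

with μ the sample mean and Σ the (unbiased) sample covariance of the
cluster.  A new hip is called *normal* when its squared Mahalanobis
distance to μ falls inside the χ²₃ quantile ellipsoid at the configured
probability (default 0.95), *abnormal* otherwise.

The knowledge-driven criterion is the classical single-angle rule:
dysplastic when θCE < 20°, normal when θCE > 25°, borderline in the closed
interval [20°, 25°]; the Tönnis > 10° rule can be combined in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.stats import chi2

from .angles import AngleTriplet
from .errors import DegenerateModelError, InputError, ModelSchemaError

__all__ = ["GaussianModel", "KnowledgeThresholds", "Diagnosis", "fit_gaussian",
           "pdf", "mahalanobis_sq", "classify_data_driven", "classify_knowledge",
           "ellipsoid_axes", "serialize_model", "load_model"]

MODEL_FORMAT_VERSION = "1"
_EIG_TOL = 1e-10


@dataclass
class GaussianModel:
    """Fitted trivariate normal model of normal hip development."""

    mu: np.ndarray          # (3,) degrees
    sigma: np.ndarray       # (3, 3) degrees², symmetric positive definite
    n_train: int
    quantile: float = 0.95

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).reshape(3)
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(3, 3)
        if not np.allclose(self.sigma, self.sigma.T, rtol=0, atol=1e-8):
            raise DegenerateModelError("covariance matrix is not symmetric")
        ev = np.linalg.eigvalsh(self.sigma)
        if ev.min() <= _EIG_TOL * max(ev.max(), 1.0):
            raise DegenerateModelError(
                f"covariance matrix is not positive definite (min eigenvalue {ev.min():g})"
            )
        if self.n_train < 4:
            raise DegenerateModelError(f"n_train must be >= 4, got {self.n_train}")
        if not 0.0 < self.quantile < 1.0:
            raise DegenerateModelError(f"quantile must be in (0,1), got {self.quantile}")

    @property
    def chi2_threshold(self) -> float:
        """Squared-Mahalanobis cutoff of the classification ellipsoid."""
        return float(chi2.ppf(self.quantile, df=3))


@dataclass
class KnowledgeThresholds:
    """Clinical single-angle thresholds (degrees)."""

    ce_dysplastic_below: float = 20.0
    ce_normal_above: float = 25.0
    tonnis_dysplastic_above: float = 10.0

    def __post_init__(self) -> None:
        if self.ce_dysplastic_below > self.ce_normal_above:
            raise InputError("ce_dysplastic_below must be <= ce_normal_above")


@dataclass(frozen=True)
class Diagnosis:
    """A classification outcome with its score and the criterion used."""

    label: str      # knowledge-driven: dysplastic|borderline|normal; data-driven: normal|abnormal
    score: float    # Mahalanobis distance (data) or CE margin to nearest threshold (knowledge)
    criterion: str  # "data_driven" | "knowledge_ce" | "knowledge_ce_tonnis"


def fit_gaussian(samples, quantile: float = 0.95) -> GaussianModel:
    """Fit μ and Σ of the trivariate normal model by sample moments.

    Uses the unbiased (n−1) covariance.  Requires at least 4 samples that
    do not all lie on a plane in angle space.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise InputError(f"samples must be (n, 3), got shape {x.shape}")
    if len(x) < 4:
        raise InputError(f"need at least 4 samples to fit, got {len(x)}")
    mu = x.mean(axis=0)
    sigma = np.cov(x, rowvar=False, ddof=1)
    try:
        return GaussianModel(mu=mu, sigma=sigma, n_train=len(x), quantile=quantile)
    except DegenerateModelError as exc:
        raise DegenerateModelError(
            f"degenerate training set (coplanar or coincident samples): {exc}"
        ) from exc


def mahalanobis_sq(model: GaussianModel, x) -> float:
    """Squared Mahalanobis distance (x−μ)ᵀ Σ⁻¹ (x−μ); zero iff x = μ."""
    d = np.asarray(x, dtype=float).reshape(3) - model.mu
    factor = cho_factor(model.sigma, lower=True)
    return float(d @ cho_solve(factor, d))


def pdf(model: GaussianModel, x) -> float:
    """The trivariate normal density at x, maximal at x = μ."""
    sign, logdet = np.linalg.slogdet(model.sigma)
    q = mahalanobis_sq(model, x)
    return float(np.exp(-0.5 * q - 0.5 * logdet - 1.5 * np.log(2.0 * np.pi)))


def classify_data_driven(model: GaussianModel, x) -> Diagnosis:
    """Classify a triplet against the model's χ²₃ quantile ellipsoid.

    Normal when the squared Mahalanobis distance is at most
    ``chi2.ppf(model.quantile, 3)``; the score is the Mahalanobis distance.
    """
    q = mahalanobis_sq(model, x)
    label = "normal" if q <= model.chi2_threshold else "abnormal"
    return Diagnosis(label=label, score=float(np.sqrt(q)), criterion="data_driven")


def classify_knowledge(
    triplet: AngleTriplet,
    thresholds: KnowledgeThresholds | None = None,
    combine_tonnis: bool = False,
) -> Diagnosis:
    """Classify by the clinical CE thresholds.

    dysplastic when θCE < ``ce_dysplastic_below``; normal when
    θCE > ``ce_normal_above``; borderline on the closed interval between
    them (the boundary values themselves are borderline).  With
    ``combine_tonnis`` the dysplastic call additionally requires
    θTönnis > ``tonnis_dysplastic_above``; a CE-dysplastic hip failing the
    Tönnis condition is demoted to borderline.
    """
    t = thresholds or KnowledgeThresholds()
    ce = triplet.ce_deg
    if ce < t.ce_dysplastic_below:
        label = "dysplastic"
        if combine_tonnis and not triplet.tonnis_deg > t.tonnis_dysplastic_above:
            label = "borderline"
    elif ce > t.ce_normal_above:
        label = "normal"
    else:
        label = "borderline"
    score = min(ce - t.ce_dysplastic_below, ce - t.ce_normal_above, key=abs)
    criterion = "knowledge_ce_tonnis" if combine_tonnis else "knowledge_ce"
    return Diagnosis(label=label, score=float(score), criterion=criterion)


def ellipsoid_axes(model: GaussianModel, quantile: float | None = None):
    """Principal axes of the classification ellipsoid.

    Returns three ``(direction, half_length)`` pairs sorted by descending
    half-length; the first is the ellipsoid's long axis.  Half-lengths are
    ``sqrt(eigenvalue * chi2.ppf(quantile, 3))``.
    """
    q = model.quantile if quantile is None else quantile
    scale = float(chi2.ppf(q, df=3))
    evals, evecs = eigh(model.sigma)
    idx = np.argsort(evals)[::-1]
    return [(evecs[:, i].copy(), float(np.sqrt(evals[i] * scale))) for i in idx]


def serialize_model(model: GaussianModel, path: str | Path) -> None:
    """Write the model as JSON (lossless round-trip of all parameters)."""
    doc = {
        "mu": model.mu.tolist(),
        "sigma": model.sigma.tolist(),
        "n_train": int(model.n_train),
        "quantile": float(model.quantile),
        "version": MODEL_FORMAT_VERSION,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> GaussianModel:
    """Read a model JSON file, re-validating all invariants."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelSchemaError(f"model file {path} is not valid JSON: {exc}") from exc
    for key in ("mu", "sigma", "n_train", "quantile"):
        if key not in doc:
            raise ModelSchemaError(f"model file {path} missing field {key!r}")
    try:
        return GaussianModel(mu=np.array(doc["mu"], dtype=float),
                             sigma=np.array(doc["sigma"], dtype=float),
                             n_train=int(doc["n_train"]),
                             quantile=float(doc["quantile"]))
    except (DegenerateModelError, ValueError) as exc:
        raise ModelSchemaError(f"invalid model in {path}: {exc}") from exc
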