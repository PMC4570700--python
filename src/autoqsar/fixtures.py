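"""Seeded synthetic datasets with known ground truth.

Four response surfaces cover the pipeline's behaviours:

* linear     — y = Xβ + ε on i.i.d. standard-normal features, with a
               documented population R² = βᵀβ/(βᵀβ + σ²);
* collinear  — a linear response plus planted pathological columns
               (a constant, a 95/5 near-zero-variance column, an exact
               duplicate pair) to exercise the dataset filters;
* nonlinear  — the Friedman benchmark surface
               y = 10·sin(π·x₁·x₂) + 20·(x₃−0.5)² + 10·x₄ + 5·x₅ + ε
               on Uniform(0,1) features, where interaction and curvature
               favour flexible learners over linear ones;
* null       — a pure-noise response independent of every feature.

All generators are pure functions of their spec: same seed, same bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import Dataset


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    kind: str  # linear | collinear | nonlinear | null
    n: int = 200
    p_informative: int = 3
    p_noise: int = 7
    coefficients: list[float] = field(default_factory=lambda: [1.0, 1.0, 1.0])
    noise_sd: float = 0.577  # with β=(1,1,1): population R² ≈ 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "collinear", "nonlinear", "null"):
            raise FixtureError(f"unknown fixture kind {self.kind!r}")
        if self.noise_sd < 0:
            raise FixtureError("noise_sd must be >= 0")
        if self.kind == "linear" and len(self.coefficients) != self.p_informative:
            raise FixtureError("need one coefficient per informative feature")


def population_r2(coefficients, noise_sd: float) -> float:
    """βᵀβ/(βᵀβ + σ²) for standard-normal i.i.d. features."""
    b = np.asarray(coefficients, dtype=float)
    signal = float(b @ b)
    return signal / (signal + noise_sd**2) if signal + noise_sd**2 > 0 else 0.0


def make_linear(spec: FixtureSpec) -> tuple[Dataset, dict]:
    """Linear response with known support and population R²."""
    if spec.kind != "linear":
        raise FixtureError("spec.kind must be 'linear'")
    rng = np.random.default_rng(spec.seed)
    p = spec.p_informative + spec.p_noise
    X = rng.standard_normal((spec.n, p))
    beta = np.concatenate([np.asarray(spec.coefficients, float), np.zeros(spec.p_noise)])
    y = X @ beta + spec.noise_sd * rng.standard_normal(spec.n)
    names = [f"inf{j + 1}" for j in range(spec.p_informative)] + [
        f"noise{j + 1}" for j in range(spec.p_noise)
    ]
    ds = Dataset(response_name="y", y=y, feature_names=names, X=X)
    meta = {
        "informative_features": names[: spec.p_informative],
        "coefficients": list(map(float, spec.coefficients)),
        "noise_sd": spec.noise_sd,
        "population_r2": population_r2(spec.coefficients, spec.noise_sd),
    }
    return ds, meta


def make_collinear(spec: FixtureSpec) -> tuple[Dataset, dict]:
    """Linear response plus planted filter-fodder columns.

    Planted pathologies (names in the returned manifest):
    ``const`` (one unique value), ``nzv95`` (95% one level, 5% another —
    frequency ratio 19, 2 unique values), and the exact duplicate pair
    ``dup_a``/``dup_b``.  The independent columns survive default
    preprocessing; exactly one of the duplicate pair is removed.
    """
    if spec.kind != "collinear":
        raise FixtureError("spec.kind must be 'collinear'")
    if spec.n < 40 or spec.n % 20:
        raise FixtureError("collinear fixture needs n a multiple of 20, >= 40")
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    k = max(2, spec.p_noise)
    indep = rng.standard_normal((n, k))
    dup = rng.standard_normal(n)
    const = np.full(n, 3.14)
    nzv = np.zeros(n)
    nzv[rng.choice(n, n // 20, replace=False)] = 1.0  # 95/5 split
    y = 2.0 * dup + indep[:, 0] + spec.noise_sd * rng.standard_normal(n)
    names = ["const", "nzv95", "dup_a", "dup_b"] + [f"ind{j + 1}" for j in range(k)]
    X = np.column_stack([const, nzv, dup, dup.copy(), indep])
    ds = Dataset(response_name="y", y=y, feature_names=names, X=X)
    manifest = {
        "constant": "const",
        "near_zero_variance": "nzv95",
        "duplicate_pair": ("dup_a", "dup_b"),
        "independent": names[4:],
    }
    return ds, manifest


def make_nonlinear(spec: FixtureSpec) -> tuple[Dataset, dict]:
    """Friedman surface: interactions + curvature that defeat linear fits.

    Uses the benchmark's canonical form: ten Uniform(0,1) inputs of which
    only the first five enter the response; ``p_informative``/``p_noise``
    are ignored for this kind.
    """
    if spec.kind != "nonlinear":
        raise FixtureError("spec.kind must be 'nonlinear'")
    rng = np.random.default_rng(spec.seed)
    p = 10
    X = rng.uniform(0.0, 1.0, size=(spec.n, p))
    signal = (
        10.0 * np.sin(np.pi * X[:, 0] * X[:, 1])
        + 20.0 * (X[:, 2] - 0.5) ** 2
        + 10.0 * X[:, 3]
        + 5.0 * X[:, 4]
    )
    y = signal + spec.noise_sd * rng.standard_normal(spec.n)
    names = [f"x{j + 1}" for j in range(p)]
    ds = Dataset(response_name="y", y=y, feature_names=names, X=X)
    meta = {
        "functional_form": "10*sin(pi*x1*x2) + 20*(x3-0.5)^2 + 10*x4 + 5*x5 + eps",
        "informative_features": names[:5],
        "noise_sd": spec.noise_sd,
    }
    return ds, meta


def make_null(spec: FixtureSpec) -> tuple[Dataset, dict]:
    """Pure-noise response: no feature carries information about y."""
    if spec.kind != "null":
        raise FixtureError("spec.kind must be 'null'")
    rng = np.random.default_rng(spec.seed)
    p = spec.p_informative + spec.p_noise
    X = rng.standard_normal((spec.n, p))
    y = rng.standard_normal(spec.n)
    names = [f"x{j + 1}" for j in range(p)]
    ds = Dataset(response_name="y", y=y, feature_names=names, X=X)
    return ds, {"population_r2": 0.0}


def make_fixture(spec: FixtureSpec) -> tuple[Dataset, dict]:
    """Dispatch on ``spec.kind``."""
    return {
        "linear": make_linear,
        "collinear": make_collinear,
        "nonlinear": make_nonlinear,
        "null": make_null,
    }[spec.kind](spec)
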