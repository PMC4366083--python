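"""Latent-trait simulation of unidimensional Likert responses.

Respondents hold positions on a single latent 0-100 continuum, drawn from one
of four population distributions (normal, skew-normal, bimodal normal mixture,
uniform).  A deterministic "true score" categorises each position through an
item's four boundaries; manifest responses then get a discretised ordinal
error: a standard-normal draw z shifts the response by 0-3 categories
according to which cutoff interval |z| falls in, in the direction sign(z),
truncated to the 1-5 range.  The design grid crosses 4 distributions x
{5, 8, 10} items x 2 error levels, with items sampled per dataset from the
27-item pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .items import ItemDefinition, load_item_pool

__all__ = [
    "DistributionSpec",
    "ErrorModel",
    "SimulationCondition",
    "LatentSample",
    "ResponseMatrix",
    "DISTRIBUTIONS",
    "ERROR_MODELS",
    "sample_latent",
    "true_score",
    "perturb",
    "generate_responses",
    "generate_dataset",
    "build_grid",
    "test_retest",
    "summarise_test_retest",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class DistributionSpec:
    """A latent population distribution over the 0-100 continuum."""

    family: str
    params: dict = field(default_factory=dict)

    _FAMILIES = ("normal", "skew_normal", "bimodal", "uniform")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        p = self.params
        if self.family == "normal" and p["sd"] <= 0:
            raise ValueError("normal sd must be positive")
        if self.family == "skew_normal" and p["scale"] <= 0:
            raise ValueError("skew-normal scale must be positive")
        if self.family == "uniform" and not p["lower"] < p["upper"]:
            raise ValueError("uniform needs lower < upper")
        if self.family == "bimodal":
            if p["sd1"] <= 0 or p["sd2"] <= 0:
                raise ValueError("component sds must be positive")
            if abs(p["w1"] + p["w2"] - 1.0) > 1e-12:
                raise ValueError("mixture weights must sum to 1")


#: The four study populations. Variances differ deliberately: smallest for the
#: skew-normal, largest for the uniform.
DISTRIBUTIONS: dict[str, DistributionSpec] = {
    "normal": DistributionSpec("normal", {"mean": 50.0, "sd": 20.0}),
    "skew_normal": DistributionSpec(
        "skew_normal", {"location": 15.0, "scale": 25.0, "shape": 5.0}
    ),
    "bimodal": DistributionSpec(
        "bimodal",
        {"mean1": 25.0, "sd1": 10.0, "mean2": 75.0, "sd2": 10.0, "w1": 0.5, "w2": 0.5},
    ),
    "uniform": DistributionSpec("uniform", {"lower": 0.0, "upper": 100.0}),
}


@dataclass(frozen=True)
class ErrorModel:
    """Discretised ordinal response error.

    ``cutoffs`` partition |z| of a standard-normal draw into shifts of
    0, 1, 2 or 3 categories; 'large' uses (1, 2, 3), 'small' (1.2, 2.2, 3).
    """

    level: str
    cutoffs: tuple[float, float, float]

    def __post_init__(self) -> None:
        c = np.asarray(self.cutoffs, dtype=float)
        if c.shape != (3,):
            raise ValueError("exactly 3 cutoffs (max perturbation 3 categories)")
        if not (np.all(np.diff(c) > 0) and c[0] > 0):
            raise ValueError("cutoffs must be ascending and positive")


ERROR_MODELS: dict[str, ErrorModel] = {
    "large": ErrorModel("large", (1.0, 2.0, 3.0)),
    "small": ErrorModel("small", (1.2, 2.2, 3.0)),
}


@dataclass(frozen=True)
class SimulationCondition:
    """One cell/replicate of the design grid."""

    distribution: DistributionSpec
    n_items: int
    error: ErrorModel
    replicate: int
    seed: int
    n_respondents: int = 2000
    distribution_name: str = ""

    def __post_init__(self) -> None:
        if self.n_respondents < 2:
            raise ValueError("need at least 2 respondents")
        if self.n_items < 1:
            raise ValueError("need at least 1 item")


@dataclass(frozen=True)
class LatentSample:
    positions: np.ndarray
    spec: DistributionSpec


@dataclass(frozen=True)
class ResponseMatrix:
    """n x p integer responses (1..5) plus sampled items and condition."""

    responses: np.ndarray
    items: tuple[ItemDefinition, ...]
    condition: SimulationCondition

    def __post_init__(self) -> None:
        r = self.responses
        if r.ndim != 2 or r.shape[1] != len(self.items):
            raise ValueError("responses must be n x p with one column per item")
        if len({it.item_id for it in self.items}) != len(self.items):
            raise ValueError("item ids must be distinct")

    @property
    def item_ids(self) -> list[int]:
        return [it.item_id for it in self.items]


# ---------------------------------------------------------------------------
# operations


def sample_latent(
    spec: DistributionSpec, n: int, seed: int | np.random.Generator
) -> LatentSample:
    """Draw n i.i.d. latent respondent positions from ``spec``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p = spec.params
    if spec.family == "normal":
        x = rng.normal(p["mean"], p["sd"], size=n)
    elif spec.family == "skew_normal":
        # Azzalini location/scale/shape parameterisation
        x = stats.skewnorm.rvs(
            p["shape"], loc=p["location"], scale=p["scale"], size=n, random_state=rng
        )
    elif spec.family == "bimodal":
        # component membership is Bernoulli per respondent
        second = rng.random(n) < p["w2"]
        x = np.where(
            second,
            rng.normal(p["mean2"], p["sd2"], size=n),
            rng.normal(p["mean1"], p["sd1"], size=n),
        )
    elif spec.family == "uniform":
        x = rng.uniform(p["lower"], p["upper"], size=n)
    else:  # pragma: no cover - guarded by DistributionSpec
        raise ValueError(spec.family)
    return LatentSample(positions=x, spec=spec)


def true_score(position, item: ItemDefinition):
    """Deterministic categorisation of a latent position by an item.

    Returns 1 + the number of boundaries <= position: category k+1 includes
    its lower boundary, so e.g. position 33 on boundaries (13,21,29,36) -> 4.
    Accepts scalars or arrays.
    """
    b = np.asarray(item.boundaries, dtype=float)
    scores = 1 + np.searchsorted(b, np.asarray(position, dtype=float), side="right")
    return scores if np.ndim(position) else int(scores)


def perturb(true_category, z, error: ErrorModel):
    """Apply the discretised ordinal error to true categories.

    The shift is the number of cutoffs strictly below |z| (0 for |z| <= c1,
    ..., 3 for |z| > c3), applied in the direction sign(z) and clamped to
    the 1..5 range.  Accepts scalars or arrays (broadcast together).
    """
    c = np.asarray(true_category)
    z = np.asarray(z, dtype=float)
    shift = np.searchsorted(np.asarray(error.cutoffs), np.abs(z), side="left")
    out = np.clip(c + np.sign(z).astype(int) * shift, 1, 5).astype(int)
    return out if out.ndim else int(out)


def generate_responses(
    latent: LatentSample,
    items: Sequence[ItemDefinition],
    error: ErrorModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Error-perturbed responses of one latent sample to a set of items.

    The error draws are independent per respondent x item and leave the
    latent sample untouched.
    """
    pos = latent.positions
    true = np.column_stack([true_score(pos, it) for it in items])
    z = rng.standard_normal(true.shape)
    return perturb(true, z, error)


def generate_dataset(
    condition: SimulationCondition, pool: Sequence[ItemDefinition] | None = None
) -> ResponseMatrix:
    """Simulate one dataset: fresh latent sample, item subset, responses."""
    pool = list(load_item_pool() if pool is None else pool)
    if condition.n_items > len(pool):
        raise ValueError("n_items exceeds the item pool size")
    rng = np.random.default_rng(condition.seed)
    latent = sample_latent(condition.distribution, condition.n_respondents, rng)
    idx = rng.choice(len(pool), size=condition.n_items, replace=False)
    items = tuple(pool[i] for i in idx)
    responses = generate_responses(latent, items, condition.error, rng)
    return ResponseMatrix(responses=responses, items=items, condition=condition)


def build_grid(
    master_seed: int,
    replicates: int | dict[int, int] = 100,
    distributions: dict[str, DistributionSpec] | None = None,
    n_items: Iterable[int] = (5, 8, 10),
    errors: dict[str, ErrorModel] | None = None,
    n_respondents: int = 2000,
) -> list[SimulationCondition]:
    """Build the design grid with deterministic per-condition seeds.

    ``replicates`` may be a single count per cell (default 100, the full
    study: 4 x 3 x 2 x 100 = 2400 datasets) or a mapping from item count to
    replicate count for scaled-down runs.
    """
    distributions = DISTRIBUTIONS if distributions is None else distributions
    errors = ERROR_MODELS if errors is None else errors
    n_items = list(n_items)
    if not (distributions and n_items and errors):
        raise ValueError("grid must have at least one distribution/item count/error level")
    reps = {p: replicates for p in n_items} if isinstance(replicates, int) else dict(replicates)
    if any(reps.get(p, 0) < 1 for p in n_items):
        raise ValueError("every cell needs at least one replicate")
    rng = np.random.default_rng(master_seed)
    conditions = []
    for dist_name, dist in distributions.items():
        for p in n_items:
            for err in errors.values():
                for r in range(reps[p]):
                    conditions.append(
                        SimulationCondition(
                            distribution=dist,
                            n_items=p,
                            error=err,
                            replicate=r,
                            seed=int(rng.integers(0, 2**31 - 1)),
                            n_respondents=n_respondents,
                            distribution_name=dist_name,
                        )
                    )
    return conditions


def test_retest(
    spec: DistributionSpec,
    error: ErrorModel,
    seed: int,
    pool: Sequence[ItemDefinition] | None = None,
    n_respondents: int = 2000,
) -> pd.DataFrame:
    """Per-item test-retest correlations for the whole pool.

    One latent sample is reused for two independently error-perturbed
    response sets; the correlation between the sets is the item's
    test-retest stability, in both Pearson and polychoric form.  Items
    degenerate in either set (a single observed category) are left missing.
    """
    from .correlations import pairwise_pearson, polychoric_pair

    pool = list(load_item_pool() if pool is None else pool)
    rng = np.random.default_rng(seed)
    latent = sample_latent(spec, n_respondents, rng)
    set1 = generate_responses(latent, pool, error, rng)
    set2 = generate_responses(latent, pool, error, rng)
    rows = []
    for j, it in enumerate(pool):
        a, b = set1[:, j], set2[:, j]
        if a.min() == a.max() or b.min() == b.max():
            rows.append((it.item_id, np.nan, np.nan))
            continue
        rho, ok = polychoric_pair(a, b)
        rows.append((it.item_id, pairwise_pearson(a, b), rho if ok else np.nan))
    return pd.DataFrame(rows, columns=["item_id", "pearson", "polychoric"])


def summarise_test_retest(table: pd.DataFrame) -> pd.DataFrame:
    """Mean / min / max / spread of the per-item test-retest correlations."""
    out = {}
    for kind in ("pearson", "polychoric"):
        v = table[kind].dropna()
        out[kind] = {
            "mean": v.mean(),
            "minimum": v.min(),
            "maximum": v.max(),
            "spread": v.max() - v.min(),
        }
    return pd.DataFrame(out)
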