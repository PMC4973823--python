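"""Synthetic populations for simulation studies and fixtures.

The central generator emulates a two-area population with individually
varying gregariousness: each animal gets a Poisson-distributed
gregariousness score (area 2 slightly more gregarious than area 1), sex is
allocated with a probability of being male that increases with
gregariousness, and in each sampling period two animals of the same area
interact with probability proportional to their combined gregariousness
(animals in different areas never interact).  Groups for gambit-of-the-group
pipelines are the connected components of each period's interaction graph.
A detection-bias layer thins observations per class (e.g. females seen with
70% reliability, conspicuous males always), which removes an undetected
animal and its interactions from that period — the classic route by which
sampling bias masquerades as a sex difference in sociality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import AttributeTable, GroupByIndividual, IndividualRegistry

logger = logging.getLogger("asna")

__all__ = [
    "PopulationSpec",
    "DetectionSpec",
    "SimulatedPopulation",
    "simulate_population",
    "apply_detection_bias",
    "events_to_gbi",
    "gamma_association_probabilities",
    "simulate_true_association_network",
    "subsample_individuals",
    "box4_dataset",
    "box5_dataset",
]


@dataclass
class PopulationSpec:
    """Parameters of the two-area gregariousness simulation.

    ``gregariousness_means`` are the per-area Poisson means (dimensionless
    propensity scores); ``edge_prob_scale`` converts a dyad's combined
    gregariousness into a per-period interaction probability, and
    ``sex_link`` is the logistic slope of P(male) on centred gregariousness:
    P(male) = expit(sex_link * (g - mean(g))).  0 makes sex independent of
    gregariousness; the steep default makes being male track above-average
    gregariousness closely, giving the sex-effect scenario a clearly
    detectable signal.
    """

    n_individuals: int = 40
    n_areas: int = 2
    gregariousness_means: tuple = (2.0, 3.0)
    sex_link: float = 6.0
    n_periods: int = 100
    edge_prob_scale: float = 0.02
    seed: int | None = None

    def __post_init__(self):
        if len(self.gregariousness_means) != self.n_areas:
            raise ValueError("one gregariousness mean per area is required")
        if any(m <= 0 for m in self.gregariousness_means):
            raise ValueError("Poisson gregariousness means must be > 0")
        if self.n_individuals < self.n_areas * 2:
            raise ValueError("need at least two individuals per area")


@dataclass
class DetectionSpec:
    """Per-class detection probabilities, keyed by an attribute column."""

    probabilities: dict = field(default_factory=lambda: {"female": 0.7, "male": 1.0})
    class_column: str = "sex"

    def __post_init__(self):
        for cls, p in self.probabilities.items():
            if not 0 <= p <= 1:
                raise ValueError(f"detection probability for {cls!r} outside [0, 1]")


@dataclass
class SimulatedPopulation:
    """Per-period dyadic events plus ground truth.

    ``events`` has integer columns ``period``, ``i``, ``j`` (registry
    positions, i < j); ``detected[p, k]`` says whether individual k was
    observable in period p (all True before detection bias).
    """

    events: pd.DataFrame
    detected: np.ndarray
    attributes: AttributeTable
    registry: IndividualRegistry
    spec: PopulationSpec

    @property
    def n_periods(self) -> int:
        return self.detected.shape[0]


def simulate_population(spec: PopulationSpec) -> SimulatedPopulation:
    """Draw a population and its per-period interaction events.

    Within-area dyads interact each period independently with probability
    ``edge_prob_scale * (g_i + g_j)`` (clipped to [0, 1] with the clip rate
    logged); cross-area dyads never interact.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals
    area = np.repeat(np.arange(spec.n_areas), int(np.ceil(n / spec.n_areas)))[:n]
    greg = rng.poisson(np.asarray(spec.gregariousness_means)[area]).astype(float)
    if not greg.any():
        raise ValueError("all gregariousness scores are zero; no interactions possible")
    p_male = expit(spec.sex_link * (greg - greg.mean())) if spec.sex_link != 0 \
        else np.full(n, 0.5)
    sex = np.where(rng.random(n) < p_male, "male", "female")

    iu, ju = np.triu_indices(n, k=1)
    same_area = area[iu] == area[ju]
    iu, ju = iu[same_area], ju[same_area]
    p = spec.edge_prob_scale * (greg[iu] + greg[ju])
    clipped = (p > 1).mean()
    if clipped:
        logger.warning("%.1f%% of dyadic probabilities clipped at 1", 100 * clipped)
    p = np.clip(p, 0.0, 1.0)

    hits = rng.random((spec.n_periods, len(iu))) < p[None, :]
    pp, dd = np.nonzero(hits)
    events = pd.DataFrame({"period": pp.astype(int), "i": iu[dd], "j": ju[dd]})

    registry = IndividualRegistry([f"id{k:03d}" for k in range(n)])
    attributes = AttributeTable(registry, {
        "sex": sex, "area": [f"area{a + 1}" for a in area], "gregariousness": greg,
    })
    detected = np.ones((spec.n_periods, n), dtype=bool)
    return SimulatedPopulation(events, detected, attributes, registry, spec)


def apply_detection_bias(pop: SimulatedPopulation, spec: DetectionSpec,
                         seed: int | None = None) -> SimulatedPopulation:
    """Thin observations per class: undetected animals lose that period's events."""
    classes = pop.attributes.column(spec.class_column)
    missing = sorted(set(classes) - set(spec.probabilities))
    if missing:
        raise ValueError(f"detection probabilities missing for classes {missing}")
    probs = np.array([spec.probabilities[c] for c in classes])
    rng = np.random.default_rng(seed)
    detected = pop.detected & (rng.random(pop.detected.shape) < probs[None, :])
    ev = pop.events
    keep = detected[ev["period"], ev["i"]] & detected[ev["period"], ev["j"]]
    return SimulatedPopulation(ev[keep].reset_index(drop=True), detected,
                               pop.attributes, pop.registry, pop.spec)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def events_to_gbi(pop: SimulatedPopulation, include_singletons: bool = True,
                  grouping: str = "components") -> GroupByIndividual:
    """Gambit-of-the-group encoding of the simulated events.

    Each period's interaction graph (among detected animals) is partitioned
    into connected components, one group row per component; detected animals
    with no interactions that period become singleton rows when
    ``include_singletons`` (they were identified, just alone).
    ``grouping='pairs'`` instead emits one row per dyadic event.  Row
    locations carry the group's area.
    """
    n = len(pop.registry)
    areas = pop.attributes.column("area")
    rows, meta = [], {"period": [], "time": [], "location": []}
    ev = pop.events
    by_period = {p: sub for p, sub in ev.groupby("period")}
    for p in range(pop.n_periods):
        det = pop.detected[p]
        sub = by_period.get(p)
        groups: list[np.ndarray] = []
        if grouping == "components":
            uf = _UnionFind(n)
            if sub is not None:
                for i, j in zip(sub["i"].to_numpy(), sub["j"].to_numpy()):
                    uf.union(int(i), int(j))
            comp: dict[int, list[int]] = {}
            linked = np.zeros(n, dtype=bool)
            if sub is not None:
                linked[sub["i"]] = True
                linked[sub["j"]] = True
            for k in np.where(linked & det)[0]:
                comp.setdefault(uf.find(int(k)), []).append(int(k))
            groups = [np.array(sorted(v)) for v in comp.values()]
            groups.sort(key=lambda g: int(g[0]))
            if include_singletons:
                for k in np.where(det & ~linked)[0]:
                    groups.append(np.array([k]))
        elif grouping == "pairs":
            if sub is not None:
                groups = [np.array([int(i), int(j)])
                          for i, j in zip(sub["i"], sub["j"])]
            if include_singletons:
                linked = np.zeros(n, dtype=bool)
                if sub is not None:
                    linked[sub["i"]] = True
                    linked[sub["j"]] = True
                for k in np.where(det & ~linked)[0]:
                    groups.append(np.array([k]))
        else:
            raise ValueError("grouping must be 'components' or 'pairs'")
        for g in groups:
            row = np.zeros(n, dtype=np.uint8)
            row[g] = 1
            rows.append(row)
            meta["period"].append(f"P{p:04d}")
            meta["time"].append(float(p))
            meta["location"].append(areas[g[0]])
    if not rows:
        raise ValueError("no observations at all (every animal undetected everywhere)")
    return GroupByIndividual(np.vstack(rows), pd.DataFrame(meta), pop.registry)


def gamma_association_probabilities(n_dyads: int, S: float, mean_p: float,
                                    rng: np.random.Generator) -> np.ndarray:
    """Gamma draws with mean ``mean_p`` and CV ``S``, clipped to [0, 1].

    The gamma family is non-negative and parameterizes the CV directly
    (shape 1/S^2, scale mean_p * S^2).  Raises when clipping would remove
    more than 10% of the distribution's mass, i.e. when the requested mean
    and CV are not jointly representable as probabilities.
    """
    if S <= 0 or not 0 < mean_p < 1:
        raise ValueError("require S > 0 and 0 < mean_p < 1")
    raw = rng.gamma(shape=1.0 / S**2, scale=mean_p * S**2, size=n_dyads)
    over = raw > 1
    if raw.sum() > 0 and (raw[over] - 1).sum() / raw.sum() > 0.10:
        raise ValueError(
            "mean_p and S force heavy clipping at probability 1; use a smaller mean_p"
        )
    if over.any():
        logger.info("clipped %d/%d dyadic probabilities at 1", int(over.sum()), n_dyads)
    return np.clip(raw, 0.0, 1.0)


def simulate_true_association_network(N: int, S: float, mean_p: float = 0.05,
                                      seed: int | None = None) -> np.ndarray:
    """Symmetric matrix of true dyadic association probabilities (zero diagonal)."""
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(N, k=1)
    p = gamma_association_probabilities(len(iu), S, mean_p, rng)
    mat = np.zeros((N, N))
    mat[iu, ju] = p
    return mat + mat.T


def subsample_individuals(gbi: GroupByIndividual, fraction: float,
                          seed: int | None = None) -> GroupByIndividual:
    """Uniformly retain a fraction of individuals (missing-individual studies).

    Keeps ``ceil(fraction * N)`` individuals; group rows emptied by the
    removal are dropped.  The retained set is reproducible from the seed.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n = gbi.n_individuals
    n_keep = int(np.ceil(fraction * n))
    if n_keep < 2:
        raise ValueError("fraction too small: fewer than 2 individuals retained")
    if n_keep == n:
        return gbi.copy()
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=n_keep, replace=False))
    registry = IndividualRegistry([gbi.registry.ids[k] for k in keep])
    matrix = gbi.matrix[:, keep]
    nonempty = matrix.sum(axis=1) > 0
    return GroupByIndividual(matrix[nonempty],
                             gbi.row_meta.iloc[nonempty].reset_index(drop=True),
                             registry)


def box4_dataset(seed: int | None = None, **overrides):
    """Sex-effect scenario: gregariousness (and hence sociality) predicts sex.

    Returns ``(gbi, attributes)`` ready for the permutation-corrected
    coefficient test of ``strength ~ sex + (1|area)``.
    """
    spec = replace(PopulationSpec(seed=seed), **overrides)
    pop = simulate_population(spec)
    return events_to_gbi(pop, include_singletons=False), pop.attributes


def box5_dataset(seed: int | None = None, detection: DetectionSpec | None = None,
                 **overrides):
    """Detection-bias scenario: no true sex effect, females under-observed.

    Sex is allocated independently of gregariousness (``sex_link=0``), then
    per-class detection thinning is applied.  The naive model typically
    reports a spurious sex effect; the data-stream permutation test should
    not.
    """
    spec = replace(PopulationSpec(seed=seed, sex_link=0.0), **overrides)
    pop = simulate_population(spec)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    biased = apply_detection_bias(pop, detection or DetectionSpec(),
                                  seed=int(rng.integers(2**31 - 1)))
    return events_to_gbi(biased, include_singletons=False), pop.attributes
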