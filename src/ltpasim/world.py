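"""World and population initialization.

A stylized community lives on a square grid of patches (non-toroidal;
distances are plain Euclidean between patch centers).  A configured
proportion of patches are LTPA sites, each with a quality score and a
set of offered activity types.  Persons are placed on non-site patches
(several may share a patch), perceive the sites and other persons
within their perception radius, and are wired into a proximal network
of k nearest neighbors with probabilistic rewiring.

Perceived site utilities are computed once here and stay fixed for the
whole simulation: the built environment is static and the person's
"site memory" is formed at initialization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .kernel import DEFAULT_SCALE, IntentionScale, prob_to_logodds, site_utility

__all__ = [
    "ModelParams",
    "Site",
    "World",
    "Population",
    "init_world",
    "init_persons",
    "build_proximal_network",
    "build_perceived_community",
    "initialize",
    "PARAM_LABELS",
    "PARAM_FIELDS",
    "resolve_param_name",
    "default_sa_domains",
    "ROBUSTNESS_PARAMS",
]


@dataclass(frozen=True)
class ModelParams:
    """Every tunable of the model, with shipped calibrated defaults.

    The alpha weights, site density, quality distribution, network size
    and subjective-assessment distribution were calibrated against two
    literature patterns: a stable LTPA prevalence between 35 and 50%
    (close to 48%) over ten years, and a U-shaped population
    distribution of intention.  See ``docs/methods.md`` for the
    calibration protocol and rationale.
    """

    grid_side: int = 50
    n_persons: int = 2000
    prop_ltpa_sites: float = 0.025
    mean_ql: float = 0.5
    sd_ql: float = 0.2
    n_activity_types: int = 10
    perception_radius: float = 9.0
    k_network: int = 5
    p_rewire: float = 0.15
    v_mean: float = 0.35
    v_sd: float = 0.25
    alpha_p: float = 0.505
    alpha_c: float = 0.505
    alpha_b: float = 0.52
    r_env: float = 100.0
    intention_split_frac: float = 0.25
    intention_low_range: tuple[float, float] = (0.03, 0.30)
    intention_high_range: tuple[float, float] = (0.31, 0.97)
    horizon_weeks: int = 520
    behavior_coding: str = "pm1"  # "pm1": +1/-1; "01": 1/0 inside the increments

    def validate(self) -> None:
        p = self
        if p.grid_side < 1:
            raise ValueError("grid_side must be >= 1")
        if p.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if not (0.0 <= p.prop_ltpa_sites <= 1.0):
            raise ValueError("prop_ltpa_sites must lie in [0, 1]")
        n_patches = p.grid_side**2
        if n_patches - int(round(n_patches * p.prop_ltpa_sites)) < 1:
            raise ValueError("no non-site patches left to place persons on")
        if not (0.0 <= p.mean_ql <= 1.0):
            raise ValueError("mean_ql must lie in [0, 1]")
        if p.sd_ql < 0.0 or p.v_sd < 0.0:
            raise ValueError("standard deviations must be >= 0")
        if p.n_activity_types < 1:
            raise ValueError("n_activity_types must be >= 1")
        if not (0.0 <= p.perception_radius <= p.grid_side):
            raise ValueError(
                f"perception_radius must lie in [0, {p.grid_side}] "
                f"(grid side), got {p.perception_radius!r}"
            )
        if not (0 <= p.k_network < p.n_persons):
            raise ValueError("k_network must satisfy 0 <= k < n_persons")
        if not (0.0 <= p.p_rewire <= 1.0):
            raise ValueError("p_rewire must lie in [0, 1]")
        if p.v_mean <= 0.0:
            raise ValueError("v_mean must be positive")
        for name in ("alpha_p", "alpha_c", "alpha_b"):
            a = getattr(p, name)
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name} must lie strictly inside (0, 1)")
        if p.r_env <= 0.0:
            raise ValueError("r_env must be positive")
        if not (0.0 <= p.intention_split_frac <= 1.0):
            raise ValueError("intention_split_frac must lie in [0, 1]")
        scale = DEFAULT_SCALE
        for rng_name in ("intention_low_range", "intention_high_range"):
            lo, hi = getattr(p, rng_name)
            if not (scale.prob_floor <= lo <= hi <= scale.prob_ceil):
                raise ValueError(
                    f"{rng_name} must satisfy "
                    f"{scale.prob_floor} <= lo <= hi <= {scale.prob_ceil}"
                )
        if p.horizon_weeks < 0:
            raise ValueError("horizon_weeks must be >= 0")
        if p.behavior_coding not in ("pm1", "01"):
            raise ValueError("behavior_coding must be 'pm1' or '01'")

    def replace(self, **changes) -> "ModelParams":
        out = dataclasses.replace(self, **changes)
        out.validate()
        return out

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["intention_low_range"] = list(d["intention_low_range"])
        d["intention_high_range"] = list(d["intention_high_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("intention_low_range", "intention_high_range"):
            if key in d:
                d[key] = tuple(float(x) for x in d[key])
        out = cls(**d)
        out.validate()
        return out


#: report labels of the six parameters analyzed in the global
#: sensitivity analysis, mapped to ModelParams fields
PARAM_LABELS = {
    "alpha.behavior": "alpha_b",
    "perception.radius": "perception_radius",
    "alpha.network": "alpha_p",
    "alpha.comm": "alpha_c",
    "prop.ltpa.sites": "prop_ltpa_sites",
    "mean.ql": "mean_ql",
}
PARAM_FIELDS = {v: k for k, v in PARAM_LABELS.items()}


def resolve_param_name(name: str) -> str:
    """Map a report label (e.g. ``alpha.behavior``) or a field name to the field name."""
    if name in PARAM_LABELS:
        return PARAM_LABELS[name]
    if any(f.name == name for f in dataclasses.fields(ModelParams)):
        return name
    raise ValueError(f"unknown parameter name: {name!r}")


def default_sa_domains(params: ModelParams) -> dict[str, tuple[float, float]]:
    """Documented search domains of the six global-SA parameters.

    The alpha weights range over weak-evidence confidences: an
    informative observation can only push toward itself (alpha >= 0.5),
    and because behavior is re-observed every single week, confidences
    even modestly above one half compound into runaway consensus within
    a few years — a degenerate regime incompatible with the stable
    mixed prevalences the model is built around.  The habit weight
    spans [0.5, 0.53] (from no habit formation to full polarization of
    the intention distribution within the simulated decade) and the
    social weights [0.5, 0.52] (their increments act through dozens to
    hundreds of observed neighbors at once).  The perception radius
    spans its whole feasible range (0 to the grid side), the site density a
    realistic urban range (up to 3% of patches), and the mean quality
    the central band of the quality scale.
    """
    return {
        "alpha_b": (0.5, 0.53),
        "perception_radius": (0.0, float(params.grid_side)),
        "alpha_p": (0.5, 0.52),
        "alpha_c": (0.5, 0.52),
        "prop_ltpa_sites": (0.0, 0.03),
        "mean_ql": (0.3, 0.7),
    }


#: the fourteen parameters swept by the one-at-a-time robustness
#: analysis: (group, domain, integer-valued)
ROBUSTNESS_PARAMS: dict[str, tuple[str, tuple[float, float], bool]] = {
    # personal attributes
    "alpha_b": ("personal", (0.5, 0.8), False),
    "perception_radius": ("personal", (0.0, 50.0), False),
    # social environment
    "alpha_p": ("social", (0.5, 0.8), False),
    "alpha_c": ("social", (0.5, 0.8), False),
    "k_network": ("social", (1, 20), True),
    "p_rewire": ("social", (0.0, 1.0), False),
    # built environment
    "prop_ltpa_sites": ("built", (0.0, 0.25), False),
    "mean_ql": ("built", (0.0, 1.0), False),
    "sd_ql": ("built", (0.0, 0.5), False),
    "n_activity_types": ("built", (1, 10), True),
    "v_mean": ("built", (0.2, 1.0), False),
    "v_sd": ("built", (0.0, 0.5), False),
    "r_env": ("built", (10.0, 1000.0), False),
    "grid_side": ("built", (25, 100), True),
}


@dataclass(frozen=True)
class Site:
    """One LTPA site: location, quality, offered activity types."""

    location: tuple[int, int]
    quality: float
    activities: frozenset[int]


@dataclass
class World:
    """The grid and its LTPA sites (column-vectorized)."""

    grid_side: int
    site_xy: np.ndarray  # (S, 2) int patch coordinates
    site_quality: np.ndarray  # (S,) in [0, 1]
    site_activities: np.ndarray  # (S, n_activity_types) bool

    @property
    def n_sites(self) -> int:
        return self.site_xy.shape[0]

    def site(self, idx: int) -> Site:
        return Site(
            location=tuple(int(c) for c in self.site_xy[idx]),
            quality=float(self.site_quality[idx]),
            activities=frozenset(np.flatnonzero(self.site_activities[idx]).tolist()),
        )


@dataclass
class Population:
    """Per-person state, vectorized over the population.

    ``favorite`` uses -1 for "no favorite activity".  ``behavior`` is
    +1 (practiced last week) / -1 (did not).  ``utilities`` holds the
    static perceived utility of every site within the perception
    radius (the person's site memory); ``best_utility`` is NaN for
    persons who perceive no site, whose behavior is forced to -1.
    ``network`` (ego lists, k columns) and ``community`` (symmetric
    adjacency) are attached by the build functions.
    """

    xy: np.ndarray  # (N, 2) int patch coordinates
    favorite: np.ndarray  # (N,) int, -1 = none
    intention: np.ndarray  # (N,) log-odds
    behavior: np.ndarray  # (N,) int8, +1 / -1
    utilities: sparse.csr_matrix  # (N, S)
    best_utility: np.ndarray  # (N,) float, NaN if no perceived site
    has_site: np.ndarray  # (N,) bool
    network: Optional[np.ndarray] = None  # (N, k) int
    community: Optional[sparse.csr_matrix] = None  # (N, N) 0/1
    _comm_degree: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def n_persons(self) -> int:
        return self.xy.shape[0]

    @property
    def comm_degree(self) -> np.ndarray:
        if self._comm_degree is None:
            if self.community is None:
                raise ValueError("community not built yet")
            object.__setattr__(
                self, "_comm_degree",
                np.asarray(self.community.sum(axis=1)).ravel(),
            )
        return self._comm_degree

    def site_memory(self, person: int) -> list[tuple[int, float]]:
        """The person's static memory: (site id, perceived utility) pairs."""
        row = self.utilities.getrow(person)
        return list(zip(row.indices.tolist(), row.data.tolist()))

    def to_dataframe(self, scale: IntentionScale = DEFAULT_SCALE) -> pd.DataFrame:
        """Snapshot of the population for inspection/export."""
        from .kernel import practice_probability

        return pd.DataFrame(
            {
                "person": np.arange(self.n_persons),
                "x": self.xy[:, 0],
                "y": self.xy[:, 1],
                "favorite": self.favorite,
                "intention_logodds": self.intention,
                "intention_prob": practice_probability(self.intention, scale),
                "behavior": self.behavior,
                "best_utility": self.best_utility,
                "n_perceived_sites": np.diff(self.utilities.indptr),
            }
        )


def _truncated_normal(mean, sd, lo, hi, size, rng) -> np.ndarray:
    """Normal(mean, sd) truncated to [lo, hi]; degenerate when sd == 0."""
    if sd == 0.0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def init_world(params: ModelParams, rng: np.random.Generator) -> World:
    """Place LTPA sites on distinct random patches and draw their attributes.

    Quality is Normal(mean_ql, sd_ql) truncated to [0, 1]; the number of
    offered activities is uniform over 1..n_activity_types and the types
    are drawn uniformly without replacement.
    """
    params.validate()
    g = params.grid_side
    n_patches = g * g
    n_sites = int(round(n_patches * params.prop_ltpa_sites))
    if n_sites > n_patches:
        raise ValueError("more sites requested than patches available")
    flat = rng.choice(n_patches, size=n_sites, replace=False)
    site_xy = np.column_stack([flat // g, flat % g]).astype(np.int64)
    quality = _truncated_normal(params.mean_ql, params.sd_ql, 0.0, 1.0, n_sites, rng)
    acts = np.zeros((n_sites, params.n_activity_types), dtype=bool)
    for s in range(n_sites):
        count = int(rng.integers(1, params.n_activity_types + 1))
        acts[s, rng.choice(params.n_activity_types, size=count, replace=False)] = True
    return World(grid_side=g, site_xy=site_xy, site_quality=quality, site_activities=acts)


def init_persons(
    world: World, params: ModelParams, rng: np.random.Generator,
    scale: IntentionScale = DEFAULT_SCALE,
) -> Population:
    """Place persons on non-site patches and draw their attributes.

    * favorite activity: uniform over {none} + the activity types;
    * site memory: perceived utility of every site within the
      perception radius, with a subjective-assessment factor v drawn
      per person-site dyad from Normal(v_mean, v_sd) truncated at 0.01;
    * intention: a random ``intention_split_frac`` subset of the
      population draws probability-scale intention uniformly from the
      low range, the rest from the high range; stored as log-odds;
    * behavior: practiced (+1) with probability equal to the
      probability-scale intention; forced to -1 for persons without a
      perceived site.
    """
    params.validate()
    g = world.grid_side
    n = params.n_persons
    n_patches = g * g

    # persons live on non-site patches; several may share a patch
    site_flat = world.site_xy[:, 0] * g + world.site_xy[:, 1]
    free = np.setdiff1d(np.arange(n_patches), site_flat)
    if free.size == 0:
        raise ValueError("no non-site patches available for persons")
    chosen = rng.choice(free, size=n, replace=True)
    xy = np.column_stack([chosen // g, chosen % g]).astype(np.int64)

    # favorite: -1 (none) or one of the activity types, all equiprobable
    favorite = rng.integers(0, params.n_activity_types + 1, size=n) - 1

    # static site memory within the perception radius
    n_sites = world.n_sites
    if n_sites > 0:
        dist = cdist(xy.astype(float), world.site_xy.astype(float))
        within = dist <= params.perception_radius
        rows, cols = np.nonzero(within)
        v = _truncated_normal(params.v_mean, params.v_sd, 0.01, np.inf, rows.size, rng)
        fav_ok = favorite >= 0
        m = np.zeros(rows.size)
        if rows.size:
            has_fav = fav_ok[rows]
            m[has_fav] = world.site_activities[
                cols[has_fav], favorite[rows[has_fav]]
            ].astype(float)
        z = np.maximum(dist[rows, cols], 1.0)
        u = site_utility(v, world.site_quality[cols], z, m, scale)
        utilities = sparse.csr_matrix(
            (np.asarray(u, dtype=float), (rows, cols)), shape=(n, n_sites)
        )
        best = np.full(n, np.nan)
        if rows.size:
            tmp = np.full(n, -np.inf)
            np.maximum.at(tmp, rows, np.asarray(u, dtype=float))
            touched = np.unique(rows)
            best[touched] = tmp[touched]
        has_site = ~np.isnan(best)
    else:
        utilities = sparse.csr_matrix((n, 0))
        best = np.full(n, np.nan)
        has_site = np.zeros(n, dtype=bool)

    # intention: split the population, draw on the probability scale
    n_low = int(round(params.intention_split_frac * n))
    low_idx = rng.choice(n, size=n_low, replace=False)
    prob = np.empty(n)
    mask_low = np.zeros(n, dtype=bool)
    mask_low[low_idx] = True
    lo_a, lo_b = params.intention_low_range
    hi_a, hi_b = params.intention_high_range
    prob[mask_low] = rng.uniform(lo_a, lo_b, size=n_low)
    prob[~mask_low] = rng.uniform(hi_a, hi_b, size=n - n_low)
    intention = np.asarray(prob_to_logodds(prob), dtype=float)

    behavior = np.where(rng.random(n) < prob, 1, -1).astype(np.int8)
    behavior[~has_site] = -1

    return Population(
        xy=xy,
        favorite=favorite,
        intention=intention,
        behavior=behavior,
        utilities=utilities,
        best_utility=best,
        has_site=has_site,
    )


def build_proximal_network(
    xy: np.ndarray, k: int, p_rewire: float, rng: np.random.Generator
) -> np.ndarray:
    """Directed ego lists: k nearest persons, with probabilistic rewiring.

    Ties in distance are broken by a random permutation of person ids
    followed by a stable sort.  Each link is then independently
    rewired, with probability ``p_rewire``, to a uniformly random
    person outside the current ego list.
    """
    n = xy.shape[0]
    if k >= n:
        raise ValueError("k_network must be smaller than the population")
    if k == 0:
        return np.empty((n, 0), dtype=np.int64)
    d = cdist(xy.astype(float), xy.astype(float))
    perm = rng.permutation(n)
    order = np.argsort(d[:, perm], axis=1, kind="stable")
    cand = perm[order[:, : k + 1]]  # may include self (distance 0 sorts first)
    net = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        row = cand[i][cand[i] != i][:k]
        if row.size < k:  # self not among the k+1 (tied strangers shadowed it)
            extra = perm[order[i, k + 1:]]
            row = np.concatenate([row, extra[extra != i][: k - row.size]])
        net[i] = row

    # rewiring: exchange marked links for persons outside the ego list
    rewire = rng.random((n, k)) < p_rewire
    for i in np.flatnonzero(rewire.any(axis=1)):
        current = set(net[i].tolist())
        for j in np.flatnonzero(rewire[i]):
            while True:
                cand_id = int(rng.integers(0, n))
                if cand_id != i and cand_id not in current:
                    break
            current.discard(int(net[i, j]))
            current.add(cand_id)
            net[i, j] = cand_id
    return net


def build_perceived_community(xy: np.ndarray, radius: float) -> sparse.csr_matrix:
    """Symmetric adjacency of all person pairs within the radius (closed ball)."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    n = xy.shape[0]
    pts = xy.astype(float)
    pairs = cKDTree(pts).query_pairs(r=radius, output_type="ndarray")
    # query_pairs excludes co-located duplicates at r only in edge cases of
    # floating error; radius and coords are integers here so <= is exact
    if pairs.size:
        i = np.concatenate([pairs[:, 0], pairs[:, 1]])
        j = np.concatenate([pairs[:, 1], pairs[:, 0]])
        data = np.ones(i.size, dtype=np.float64)
        adj = sparse.csr_matrix((data, (i, j)), shape=(n, n))
        adj.sum_duplicates()
        adj.data[:] = 1.0
    else:
        adj = sparse.csr_matrix((n, n))
    return adj


def initialize(
    params: ModelParams, rng: np.random.Generator,
    scale: IntentionScale = DEFAULT_SCALE,
) -> tuple[World, Population]:
    """Build the world and a fully wired population (one replication's start)."""
    world = init_world(params, rng)
    pop = init_persons(world, params, rng, scale)
    pop.network = build_proximal_network(pop.xy, params.k_network, params.p_rewire, rng)
    pop.community = build_perceived_community(pop.xy, params.perception_radius)
    return world, pop
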