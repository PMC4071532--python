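"""Synthetic study system: regions, climate fields, species and extinctions.

Generates a planar world with the statistical structure the analysis assumes:
a lattice tessellated into contiguous regions grouped into continent blocks,
each continent carrying one hominin-history class; smooth spatially
autocorrelated climate fields per epoch; a species table with masses, dates
and statuses spanning every acceptance filter; and per-region extinction
counts produced on the arcsine scale by a linear predictor plus spatially
autocorrelated SAR errors.  All randomness flows through explicit seeds, so
identical configurations yield bit-identical worlds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter

from .climate import ClimateGrid
from .errors import EstimationError, InvalidConfigError
from .spatial import knn_weights

#: Hominin-history classes, ordered by length of hominin co-occurrence
#: (longest first).  The three middle classes lump into "Archaic-combined".
HOMININ_CLASSES = (
    "Homo-origin",
    "Archaic-early",
    "Archaic-late",
    "Archaic-peripheral",
    "Homo_sapiens-only",
)
ARCHAIC_CLASSES = frozenset(HOMININ_CLASSES[1:4])

#: Default continent -> hominin class map for a six-continent world.
DEFAULT_HOMININ_MAP = {
    0: "Homo-origin",
    1: "Archaic-early",
    2: "Archaic-late",
    3: "Archaic-peripheral",
    4: "Homo_sapiens-only",
    5: "Homo_sapiens-only",
}


def round_half_up(x) -> np.ndarray:
    """Deterministic round-half-up (0.5 -> 1), elementwise."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


@dataclass
class WorldConfig:
    """Configuration of the synthetic world."""

    n_regions: int = 229
    grid_shape: tuple[int, int] = (30, 30)
    cell_size_km: float = 250.0
    continents: int = 6
    hominin_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_HOMININ_MAP))
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if self.n_regions < 8:
            raise InvalidConfigError("need at least 8 regions")
        if self.n_regions > rows * cols:
            raise InvalidConfigError(
                f"{self.n_regions} regions exceed {rows * cols} lattice cells"
            )
        if self.continents < 1 or self.continents > self.n_regions:
            raise InvalidConfigError("continents must be in [1, n_regions]")
        if self.cell_size_km <= 0:
            raise InvalidConfigError("cell_size_km must be positive")
        for c in range(self.continents):
            cls = self.hominin_map.get(c)
            if cls is None:
                raise InvalidConfigError(f"continent {c} has no hominin class")
            if cls not in HOMININ_CLASSES:
                raise InvalidConfigError(f"unknown hominin class {cls!r}")


@dataclass
class RegionSet:
    """Tessellation of the lattice into regions with attributes and adjacency."""

    table: pd.DataFrame  # region_id, centroid_x_km, centroid_y_km, continent, hominin_class
    membership: np.ndarray  # (rows, cols) region id per lattice cell
    adjacency: nx.Graph  # rook adjacency between regions
    cell_size_km: float

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["centroid_x_km", "centroid_y_km"]].to_numpy()


def _block_grid(continents: int, shape: tuple[int, int]) -> tuple[int, int]:
    """Factor `continents` into a (rows, cols) block layout close to square."""
    best = (1, continents)
    for br in range(1, continents + 1):
        if continents % br == 0:
            bc = continents // br
            if abs(br - bc) < abs(best[0] - best[1]):
                best = (br, bc)
    br, bc = best
    if shape[0] < br or shape[1] < bc:
        # fall back to a strip along the longer axis
        return (continents, 1) if shape[0] >= continents else (1, continents)
    return best


def _split(n: int, parts: int) -> list[int]:
    """Split n into `parts` near-equal positive integers."""
    base, extra = divmod(n, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def generate_regions(cfg: WorldConfig) -> RegionSet:
    """Partition the lattice into contiguous regions grouped by continent.

    Continents are contiguous rectangular blocks; within each block, cells
    are walked in serpentine order and cut into near-equal contiguous runs,
    one per region, so each region and each continent is rook-connected.
    """
    rows, cols = cfg.grid_shape
    br, bc = _block_grid(cfg.continents, cfg.grid_shape)
    row_bands = np.cumsum([0] + _split(rows, br))
    col_bands = np.cumsum([0] + _split(cols, bc))

    blocks: list[list[tuple[int, int]]] = []
    for i in range(br):
        for j in range(bc):
            cells = []
            flip = False
            for r in range(row_bands[i], row_bands[i + 1]):
                cs = range(col_bands[j], col_bands[j + 1])
                cells.extend((r, c) for c in (reversed(cs) if flip else cs))
                flip = not flip
            blocks.append(cells)

    counts = [len(b) for b in blocks]
    total = sum(counts)
    # regions per continent, proportional with largest remainder, each >= 1
    raw = [cfg.n_regions * c / total for c in counts]
    alloc = [max(1, int(x)) for x in raw]
    while sum(alloc) < cfg.n_regions:
        frac = [r - a for r, a in zip(raw, alloc)]
        alloc[int(np.argmax(frac))] += 1
    while sum(alloc) > cfg.n_regions:
        frac = [r - a if a > 1 else np.inf for r, a in zip(raw, alloc)]
        alloc[int(np.argmin(frac))] -= 1
    for a, c in zip(alloc, counts):
        if a > c:
            raise InvalidConfigError("a continent block has fewer cells than regions")

    membership = np.full(cfg.grid_shape, -1, dtype=int)
    records = []
    rid = 0
    for cont, (cells, k) in enumerate(zip(blocks, alloc)):
        runs = _split(len(cells), k)
        pos = 0
        for run in runs:
            owned = cells[pos : pos + run]
            pos += run
            for r, c in owned:
                membership[r, c] = rid
            ys = np.array([r for r, _ in owned], dtype=float)
            xs = np.array([c for _, c in owned], dtype=float)
            records.append(
                {
                    "region_id": rid,
                    "centroid_x_km": float((xs.mean() + 0.5) * cfg.cell_size_km),
                    "centroid_y_km": float((ys.mean() + 0.5) * cfg.cell_size_km),
                    "continent": cont,
                    "hominin_class": cfg.hominin_map[cont],
                }
            )
            rid += 1

    adj = nx.Graph()
    adj.add_nodes_from(range(rid))
    for r in range(rows):
        for c in range(cols):
            a = membership[r, c]
            if c + 1 < cols and membership[r, c + 1] != a:
                adj.add_edge(a, membership[r, c + 1])
            if r + 1 < rows and membership[r + 1, c] != a:
                adj.add_edge(a, membership[r + 1, c])

    table = pd.DataFrame.from_records(records)
    if table[["centroid_x_km", "centroid_y_km"]].duplicated().any():
        # serpentine runs can share centroids on symmetric layouts; jitter
        # deterministically by region id (sub-metre, physically negligible)
        table["centroid_x_km"] += table["region_id"] * 1e-6
    return RegionSet(table, membership, adj, cfg.cell_size_km)


def generate_climate_field(
    cfg: WorldConfig,
    epoch: str,
    smoothness_km: float,
    seed: int,
    variable: str = "temperature",
    trend_amplitude: float = 10.0,
    noise_sd: float = 3.0,
    innovations: np.ndarray | None = None,
) -> ClimateGrid:
    """A smooth, spatially autocorrelated climate field for one epoch.

    The field is a north-south linear trend plus white noise smoothed by a
    Gaussian kernel of correlation length ``smoothness_km`` and rescaled to
    SD ``noise_sd``.  Pass ``innovations`` (a standard-normal array) to share
    or correlate innovations between epochs; with ``smoothness_km = inf`` the
    noise collapses to a spatial constant, leaving only the trend.
    """
    if smoothness_km <= 0:
        raise InvalidConfigError("smoothness must be positive")
    rows, cols = cfg.grid_shape
    if innovations is None:
        rng = np.random.default_rng(seed)
        innovations = rng.standard_normal((rows, cols))
    elif innovations.shape != (rows, cols):
        raise InvalidConfigError("innovations shape mismatch")

    yy = np.arange(rows, dtype=float)[:, None] / max(rows - 1, 1)
    trend = trend_amplitude * np.broadcast_to(yy, (rows, cols))

    if np.isinf(smoothness_km):
        noise = np.full((rows, cols), float(innovations.mean()))
    else:
        sigma_cells = smoothness_km / cfg.cell_size_km
        noise = gaussian_filter(innovations, sigma=sigma_cells, mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise = noise / sd * noise_sd
    return ClimateGrid(
        trend + noise, cfg.cell_size_km * 1000.0, epoch=epoch, variable=variable
    )


def generate_epoch_pair(
    cfg: WorldConfig,
    smoothness_km: float,
    correlation: float,
    seed: int,
    epochs: tuple[str, str] = ("lgm", "present"),
    **kwargs,
) -> tuple[ClimateGrid, ClimateGrid]:
    """Two epoch fields whose innovations correlate at ``correlation``.

    eps_b = r eps_a + sqrt(1 - r^2) eps_c with independent standard-normal
    draws, so the smoothed anomaly patterns share structure between epochs.
    """
    if not -1.0 <= correlation <= 1.0:
        raise InvalidConfigError("correlation must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    rows, cols = cfg.grid_shape
    eps_a = rng.standard_normal((rows, cols))
    eps_c = rng.standard_normal((rows, cols))
    eps_b = correlation * eps_a + np.sqrt(1 - correlation**2) * eps_c
    a = generate_climate_field(cfg, epochs[0], smoothness_km, seed, innovations=eps_a, **kwargs)
    b = generate_climate_field(cfg, epochs[1], smoothness_km, seed, innovations=eps_b, **kwargs)
    return a, b


@dataclass
class DGPParams:
    """Data-generating parameters for per-region extinction proportions.

    ``beta`` acts on the arcsine scale over the design
    (intercept, HS, AC, TA, HS x TA, AC x TA) where HS / AC indicate the
    Homo-sapiens-only / Archaic-combined classes and TA is the standardized
    temperature anomaly.  Errors follow u = lambda W u + eps with 4-NN
    row-standardized weights.  Defaults: beta from the reference fitted
    model; lambda and sigma chosen so simulated proportion spread resembles
    the observed interquartile ranges (generator defaults, not claims).
    """

    beta: np.ndarray = field(
        default_factory=lambda: np.array([-0.353, 1.107, 0.735, 1.504, -1.516, -1.225])
    )
    lam: float = 0.6
    sigma: float = 0.15
    richness_range: tuple[int, int] = (10, 60)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (6,):
            raise InvalidConfigError("beta must have 6 entries")
        if not -1.0 < self.lam < 1.0:
            raise InvalidConfigError("lambda must lie strictly inside (-1, 1)")
        if self.sigma < 0:
            raise InvalidConfigError("sigma must be nonnegative")
        if self.richness_range[0] < 1 or self.richness_range[1] < self.richness_range[0]:
            raise InvalidConfigError("richness_range min must be >= 1 and <= max")


def design_matrix(hominin_class: pd.Series | np.ndarray, ta_std: np.ndarray) -> np.ndarray:
    """(1, HS, AC, TA, HS*TA, AC*TA) design used by the generator and models."""
    cls = np.asarray(hominin_class)
    hs = (cls == "Homo_sapiens-only").astype(float)
    ac = np.isin(cls, list(ARCHAIC_CLASSES)).astype(float)
    ta = np.asarray(ta_std, dtype=float)
    return np.column_stack([np.ones_like(ta), hs, ac, ta, hs * ta, ac * ta])


def generate_extinctions(
    regions: RegionSet,
    ta_std: np.ndarray,
    params: DGPParams,
    seed: int,
) -> pd.DataFrame:
    """Per-region (total_species, extinct_count, true_proportion) from the DGP.

    eta = X beta + u with u = (I - lambda W)^(-1) eps solved exactly;
    p = sin^2(eta clamped to [0, pi/2]); extinct = round-half-up(p * total).
    """
    ta_std = np.asarray(ta_std, dtype=float)
    if np.any((ta_std < 0) | (ta_std > 1)):
        raise InvalidConfigError("ta_std must lie in [0, 1]")
    if len(ta_std) != regions.n:
        raise InvalidConfigError("ta_std length must match region count")
    rng = np.random.default_rng(seed)
    X = design_matrix(regions.table["hominin_class"], ta_std)
    eps = params.sigma * rng.standard_normal(regions.n)
    if params.lam == 0.0:
        u = eps
    else:
        W = knn_weights(regions.centroids, k=4).matrix
        A = (sp.identity(regions.n, format="csc") - params.lam * W.tocsc()).tocsc()
        try:
            u = sp.linalg.spsolve(A, eps)
        except RuntimeError as exc:  # pragma: no cover - |lam|<1 keeps A regular
            raise EstimationError(f"(I - lambda W) singular: {exc}") from exc
    eta = X @ params.beta + u
    p = np.sin(np.clip(eta, 0.0, np.pi / 2)) ** 2
    lo, hi = params.richness_range
    total = rng.integers(lo, hi + 1, size=regions.n)
    extinct = round_half_up(p * total)
    extinct = np.minimum(extinct, total)
    out = regions.table[["region_id", "continent", "hominin_class"]].copy()
    out["ta_std"] = ta_std
    out["total_species"] = total
    out["extinct_count"] = extinct
    out["true_proportion"] = p
    out["eta"] = eta
    out["sar_error"] = u
    return out


def generate_species_table(
    n_species: int,
    regions: RegionSet | None = None,
    mass_meanlog: float = 4.0,
    mass_sdlog: float = 1.6,
    window: tuple[float, float] = (132_000.0, 1_000.0),
    uncertain_fraction: float = 0.13,
    late_fraction: float = 0.06,
    undated_fraction: float = 0.04,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Species table plus binary presence matrix in long form.

    Masses are log-normal (spanning the 10 kg and 44 kg thresholds); a
    ``late_fraction`` of species is dated entirely after the study window and
    an ``undated_fraction`` lacks a direct date, so every acceptance filter
    is exercised.  Each species occupies a contiguous patch of >= 1 region.
    """
    if n_species < 1:
        raise InvalidConfigError("need at least one species")
    rng = np.random.default_rng(seed)
    masses = np.round(np.exp(rng.normal(mass_meanlog, mass_sdlog, n_species)), 1)
    masses = np.maximum(masses, 0.5)
    status = np.where(rng.random(n_species) < uncertain_fraction, "uncertain", "accepted")
    direct = rng.random(n_species) >= undated_fraction
    hi, lo = window
    late = rng.random(n_species) < late_fraction
    earliest = np.where(
        late,
        rng.uniform(lo * 0.5, lo * 0.95, n_species),
        rng.uniform(lo * 2, hi, n_species),
    )
    latest = np.where(
        late,
        rng.uniform(lo * 0.1, lo * 0.5, n_species),
        earliest * rng.uniform(0.05, 0.9, n_species),
    )
    scope = np.where(rng.random(n_species) < 0.2, "continental", "global")
    species = pd.DataFrame(
        {
            "name": [f"sp_{i:04d}" for i in range(n_species)],
            "mass_kg": masses,
            "status": status,
            "direct_date": direct,
            "earliest_bp": np.round(earliest, 0),
            "latest_bp": np.round(latest, 0),
            "scope": scope,
        }
    )

    rows = []
    if regions is not None:
        adj = regions.adjacency
        region_ids = list(regions.table["region_id"])
        for i in range(n_species):
            size = 1 + rng.geometric(0.25)
            start = region_ids[rng.integers(len(region_ids))]
            patch = [start]
            frontier = {start}
            while len(patch) < size and frontier:
                nbrs = sorted(
                    set().union(*(set(adj.neighbors(p)) for p in frontier)) - set(patch)
                )
                if not nbrs:
                    break
                nxt = nbrs[rng.integers(len(nbrs))]
                patch.append(nxt)
                frontier = set(patch)
            rows.extend(
                {"species": species.loc[i, "name"], "region_id": r, "provenance": "direct"}
                for r in patch
            )
    presence = pd.DataFrame(rows, columns=["species", "region_id", "provenance"])
    return species, presence
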