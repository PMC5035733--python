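"""Synthetic SIP gradient and isotope-series generator.

Emulates the statistical structure of an rRNA-SIP experiment: a community of
taxa with baseline relative abundances, per-taxon proportions of
13C-labeled rRNA that shift buoyant density, isopycnic fractionation into
density bins (12 fractions by default, fraction 1 the densest), multinomial
read sampling of two sequenced fractions (heavy and light), paired
12C-control gradients, and delta-13C time series that follow the linear
two-pool mixing relation exactly (plus Gaussian measurement noise).

The density of a taxon's rRNA is modeled as a two-component Gaussian
mixture: a proportion ``a`` of its molecules (the 13C-labeled ones) band at
``rho_unlabeled + delta_rho_max`` and the remaining ``1 - a`` at
``rho_unlabeled``, both with within-population spread ``sigma``. This
reflects that rRNA synthesized from a uniformly 13C-labeled substrate is
near-fully labeled while pre-existing rRNA is not, so label assimilation
moves mass between two modes rather than sliding one mode continuously.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DensityModel",
    "SimTaxon",
    "SimulationConfig",
    "GradientTable",
    "fraction_weights",
    "expected_composition",
    "simulate_gradient_pair",
    "simulate_isotope_series",
    "synthetic_reference_sequences",
    "default_config",
]


def _default_edges() -> tuple[float, ...]:
    # 12 bins spanning 1.755-1.845 g/ml: unlabeled mode (1.790) sits in
    # fraction 8 (~1.79, "light"), fully labeled mode (1.825) in fraction 3
    # (~1.82, "heavy"), matching typical CsTFA rRNA gradients.
    return tuple(np.linspace(1.755, 1.845, 13))


@dataclass(frozen=True)
class DensityModel:
    """Buoyant-density model for rRNA in an isopycnic gradient.

    Parameters
    ----------
    rho_unlabeled
        Mean buoyant density of unlabeled rRNA (g/ml).
    delta_rho_max
        Density increase of fully 13C-labeled rRNA (g/ml).
    sigma
        Within-population density standard deviation (g/ml).
    fraction_edges
        Ascending density bin boundaries (g/ml). ``len(edges) - 1``
        fractions are collected; fraction 1 is the densest bin.
    """

    rho_unlabeled: float = 1.790
    delta_rho_max: float = 0.035
    sigma: float = 0.008
    fraction_edges: tuple[float, ...] = field(default_factory=_default_edges)

    def __post_init__(self) -> None:
        edges = np.asarray(self.fraction_edges, dtype=float)
        object.__setattr__(self, "fraction_edges", tuple(float(x) for x in edges))
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.delta_rho_max < 0:
            raise ValueError("delta_rho_max must be >= 0")
        if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
            raise ValueError("fraction_edges must be strictly increasing with >=2 values")

    @property
    def n_fractions(self) -> int:
        return len(self.fraction_edges) - 1

    @property
    def fraction_densities(self) -> np.ndarray:
        """Bin midpoint density per fraction, fraction 1 (densest) first."""
        edges = np.asarray(self.fraction_edges)
        mids = 0.5 * (edges[:-1] + edges[1:])
        return mids[::-1].copy()


@dataclass(frozen=True)
class SimTaxon:
    """One simulated taxon.

    ``labeled_fraction`` maps ``(substrate, timepoint)`` to the proportion of
    the taxon's rRNA that is 13C-labeled under that treatment; cells absent
    from the mapping default to 0 (no label assimilation).
    """

    name: str
    group: str  # bacteria | fungi | protist
    baseline: float
    labeled_fraction: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in {"bacteria", "fungi", "protist"}:
            raise ValueError(f"unknown group {self.group!r} for taxon {self.name!r}")
        if not 0 <= self.baseline <= 1:
            raise ValueError(f"baseline out of [0,1] for taxon {self.name!r}")
        for key, a in dict(self.labeled_fraction).items():
            if not 0 <= a <= 1:
                raise ValueError(f"labeled_fraction {a} out of [0,1] for {self.name!r} at {key}")

    def labeled_at(self, substrate: str, timepoint: str) -> float:
        return float(dict(self.labeled_fraction).get((substrate, timepoint), 0.0))


@dataclass(frozen=True)
class SimulationConfig:
    taxa: tuple[SimTaxon, ...]
    density: DensityModel = field(default_factory=DensityModel)
    depth: int = 10_000
    sequenced_fractions: tuple[int, int] = (3, 8)  # (heavy, light), 1-based
    substrates: tuple[str, ...] = ("glucose", "cellulose")
    timepoints: tuple[str, ...] = ("8d", "32d")
    noise_sd_delta13c: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", tuple(self.taxa))
        object.__setattr__(self, "substrates", tuple(self.substrates))
        object.__setattr__(self, "timepoints", tuple(self.timepoints))
        object.__setattr__(self, "sequenced_fractions", tuple(self.sequenced_fractions))
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        total = sum(t.baseline for t in self.taxa)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"taxon baselines must sum to 1 (got {total})")
        n = self.density.n_fractions
        for f in self.sequenced_fractions:
            if not 1 <= f <= n:
                raise ValueError(f"sequenced fraction {f} outside 1..{n}")
        if self.noise_sd_delta13c < 0:
            raise ValueError("noise_sd_delta13c must be >= 0")

    @property
    def taxon_names(self) -> list[str]:
        return [t.name for t in self.taxa]


@dataclass
class GradientTable:
    """Taxon x fraction read counts for one gradient.

    ``counts`` is indexed by taxon with integer fraction-number columns
    (1 = densest). ``densities`` gives the bin midpoint density per column.
    """

    counts: pd.DataFrame
    densities: np.ndarray
    substrate: str
    isotope: str  # "13C" or "12C"
    timepoint: str

    @property
    def fractions(self) -> list[int]:
        return list(self.counts.columns)

    def fraction_counts(self, fraction: int) -> pd.Series:
        if fraction not in self.counts.columns:
            raise KeyError(f"fraction {fraction} not present in gradient table")
        return self.counts[fraction]


def fraction_weights(model: DensityModel, labeled_fraction: float) -> np.ndarray:
    """Per-fraction banding probabilities for rRNA with a given labeled share.

    Mass ``1 - a`` comes from Normal(rho_unlabeled, sigma) and mass ``a``
    from Normal(rho_unlabeled + delta_rho_max, sigma); each fraction's
    weight is the mixture probability inside its density bin, renormalized
    over the collected bins (mass pelleted or floated outside the binned
    range is discarded). Returned with fraction 1 (densest) first.
    """
    a = float(labeled_fraction)
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"labeled_fraction must be in [0,1], got {a}")
    edges = model.fraction_edges
    light = np.diff(norm.cdf(edges, loc=model.rho_unlabeled, scale=model.sigma))
    heavy = np.diff(
        norm.cdf(edges, loc=model.rho_unlabeled + model.delta_rho_max, scale=model.sigma)
    )
    w = (1.0 - a) * light + a * heavy
    total = w.sum()
    if total <= 0:
        raise ValueError("no probability mass inside the binned density range")
    return (w / total)[::-1].copy()  # fraction 1 = densest


def expected_composition(
    config: SimulationConfig, labeled_fractions: Sequence[float]
) -> pd.DataFrame:
    """Expected relative abundance of each taxon in each fraction (no sampling).

    ``labeled_fractions`` is one labeled proportion per taxon, in config
    order. Rows are taxa, columns fraction numbers; each column sums to 1.
    """
    if len(labeled_fractions) != len(config.taxa):
        raise ValueError("one labeled_fraction per taxon required")
    w = np.vstack(
        [fraction_weights(config.density, a) for a in labeled_fractions]
    )  # taxa x fractions
    b = np.array([t.baseline for t in config.taxa])[:, None]
    mass = b * w
    col = mass.sum(axis=0)
    if np.any(col <= 0):
        raise ValueError("a fraction received zero expected mass")
    comp = mass / col
    return pd.DataFrame(
        comp,
        index=pd.Index(config.taxon_names, name="taxon"),
        columns=pd.RangeIndex(1, config.density.n_fractions + 1),
    )


def _sample_gradient(
    config: SimulationConfig,
    labeled_fractions: Sequence[float],
    substrate: str,
    isotope: str,
    timepoint: str,
    rng: np.random.Generator,
) -> GradientTable:
    comp = expected_composition(config, labeled_fractions)
    counts = np.empty_like(comp.values, dtype=np.int64)
    for j in range(comp.shape[1]):
        counts[:, j] = rng.multinomial(config.depth, comp.values[:, j])
    table = pd.DataFrame(counts, index=comp.index.copy(), columns=comp.columns.copy())
    return GradientTable(
        counts=table,
        densities=config.density.fraction_densities,
        substrate=substrate,
        isotope=isotope,
        timepoint=timepoint,
    )


def simulate_gradient_pair(
    config: SimulationConfig,
    substrate: str,
    timepoint: str,
    rng: np.random.Generator | None = None,
) -> tuple[GradientTable, GradientTable]:
    """Simulate the 13C gradient and its paired 12C control.

    In the 13C gradient each taxon bands according to its
    ``labeled_fraction`` for this substrate and timepoint; in the 12C
    control no taxon carries label. Read counts per fraction are drawn
    multinomially at the configured depth, so each fraction's counts sum
    exactly to ``depth``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    a13 = [t.labeled_at(substrate, timepoint) for t in config.taxa]
    a12 = [0.0] * len(config.taxa)
    t13 = _sample_gradient(config, a13, substrate, "13C", timepoint, rng)
    t12 = _sample_gradient(config, a12, substrate, "12C", timepoint, rng)
    return t13, t12


def simulate_isotope_series(
    config: SimulationConfig,
    true_fraction: Mapping[tuple[str, str], float],
    delta_reference: float,
    delta_substrate: float,
    delta_soil: float,
    substrate: str = "glucose",
    n_replicates: int = 3,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate delta-13C measurements consistent with two-pool linear mixing.

    ``true_fraction`` maps ``(pool, timepoint)`` to the true proportion of
    pool carbon derived from the substrate (0-1). For each pool, timepoint
    and replicate:

        delta_sample = delta_reference
                       + f * (delta_substrate - delta_soil)
                       + Normal(0, noise_sd_delta13c)

    Returns a long-format frame with columns pool, treatment, timepoint,
    replicate, delta13C.
    """
    if delta_substrate == delta_soil:
        raise ValueError("delta_substrate must differ from delta_soil (mixing undefined)")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for (pool, timepoint), f in true_fraction.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"true_fraction {f} out of [0,1] for {(pool, timepoint)}")
        mean = delta_reference + f * (delta_substrate - delta_soil)
        noise = (
            rng.normal(0.0, config.noise_sd_delta13c, size=n_replicates)
            if config.noise_sd_delta13c > 0
            else np.zeros(n_replicates)
        )
        for r in range(n_replicates):
            rows.append(
                {
                    "pool": pool,
                    "treatment": substrate,
                    "timepoint": timepoint,
                    "replicate": r + 1,
                    "delta13C": mean + noise[r],
                }
            )
    return pd.DataFrame(rows)


_BASES = np.array(list("ACGT"))


def synthetic_reference_sequences(
    taxa: Sequence[str],
    primer: str,
    site: str,
    rng: np.random.Generator,
    length: int = 500,
    min_trf: int = 60,
    max_trf: int = 450,
) -> dict[str, str]:
    """Random reference sequences with a planted restriction site per taxon.

    Each synthetic sequence starts with the forward primer, contains one
    planted recognition ``site`` at a taxon-specific random offset and no
    earlier occurrence, so predicted T-RF lengths are distinct, known
    ground truth. Intended for demos and tests, not biology.
    """
    out: dict[str, str] = {}
    for name in taxa:
        while True:
            body = "".join(rng.choice(_BASES, size=length))
            seq = primer + body
            pos = int(rng.integers(min_trf, max_trf))
            seq = seq[:pos] + site + seq[pos + len(site):]
            if seq.find(site) == pos and len(seq) >= length:
                out[name] = seq[:length]
                break
    return out


def default_config(seed: int = 0, depth: int = 10_000) -> SimulationConfig:
    """Default simulated detritusphere community.

    Twelve taxa across bacteria, fungi and protists with a mildly uneven
    abundance profile; a few taxa assimilate label strongly (labeled rRNA
    proportion up to 0.8) on specific substrates and timepoints, the rest
    form an unlabeled background.
    """
    lf = lambda **kw: {  # noqa: E731 - tiny local literal helper
        tuple(k.split("__")): v for k, v in kw.items()
    }
    taxa = (
        SimTaxon("Arthrobacter", "bacteria", 0.14, lf(glucose__8d=0.8, glucose__32d=0.8)),
        SimTaxon("Cellvibrio", "bacteria", 0.06, lf(cellulose__8d=0.8, cellulose__32d=0.4)),
        SimTaxon("Flavobacterium", "bacteria", 0.08, lf(cellulose__8d=0.6)),
        SimTaxon("Kitasatospora", "bacteria", 0.04, lf(cellulose__32d=0.7)),
        SimTaxon("Micrococcaceae", "bacteria", 0.10, lf(glucose__8d=0.3, glucose__32d=0.5)),
        SimTaxon("Bacterium_bg1", "bacteria", 0.10),
        SimTaxon("Bacterium_bg2", "bacteria", 0.09),
        SimTaxon("Bacterium_bg3", "bacteria", 0.08),
        SimTaxon("Bacterium_bg4", "bacteria", 0.07),
        SimTaxon("Cryptococcus", "fungi", 0.09, lf(glucose__8d=0.8, glucose__32d=0.7)),
        SimTaxon("Chaetomium", "fungi", 0.08, lf(cellulose__8d=0.6)),
        SimTaxon("Pythium", "protist", 0.07, lf(glucose__8d=0.7, glucose__32d=0.5)),
    )
    return SimulationConfig(taxa=taxa, depth=depth, seed=seed)


def config_to_dict(config: SimulationConfig) -> dict:
    """JSON-serializable echo of a simulation config (for sidecar metadata)."""
    d = dataclasses.asdict(config)
    d["density"]["fraction_edges"] = [float(x) for x in config.density.fraction_edges]
    d["taxa"] = [
        {
            "name": t.name,
            "group": t.group,
            "baseline": t.baseline,
            "labeled_fraction": {f"{s}|{tp}": v for (s, tp), v in dict(t.labeled_fraction).items()},
        }
        for t in config.taxa
    ]
    return d
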