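"""Synthetic compound-descriptor and sub-pocket generators.

The published analysis is built on curated compound collections (iPPI-DB,
TIMBAL, MDDR, BindingDB subsets, ...) whose descriptor tables cannot be
redistributed.  This module generates descriptor tables with the same
first- and second-moment structure — per-descriptor mean, SD and physical
bounds — so that every downstream stage (statistical comparison, PCA,
overlap scoring, clustering) is exercisable without any download.

Marginals are truncated Gaussians: the only distributional information
available for the reference collections is a mean ± SD per descriptor, and
physically bounded descriptors (ratios, globularity) are kept inside their
ranges by rejection sampling.  Because the published mean ± SD describe the
*observed* (in-bounds) values, the parent Gaussian of a bounded descriptor
is moment-calibrated so that the truncated distribution itself has the
requested mean and SD.  Cross-descriptor correlation defaults to the
identity matrix and can be supplied explicitly for stress tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: The seven descriptors reported to discriminate PPI inhibitors from
#: conventional actives: size, hydrophobicity, aromaticity and four 3D
#: shape descriptors.
DISCRIMINATIVE_DESCRIPTORS = (
    "MW",
    "AlogP",
    "aromatic_ratio",
    "CW2",
    "IW4",
    "glob",
    "EDmin3",
)

_UNBOUNDED = (-np.inf, np.inf)

#: Default physical bounds per descriptor.  Aromatic ratio is a proportion,
#: globularity is a strictly positive isotropy measure capped at 1 (a
#: sphere), molecular weight is strictly positive.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "MW": (0.0, np.inf),
    "aromatic_ratio": (0.0, 1.0),
    "glob": (0.0, 1.0),
}


@dataclass
class DatasetSpec:
    """Generative parameters for one synthetic compound collection.

    Parameters
    ----------
    name
        Dataset label (e.g. ``"iPPI-DB"``).
    n
        Number of compounds to generate.
    means, sds
        Per-descriptor mean and standard deviation.  Units follow the
        descriptor: MW in g/mol, EDmin3 in kcal/mol, ratios unitless.
    bounds
        Per-descriptor ``(lower, upper)`` truncation interval; descriptors
        not listed are unbounded.
    correlation
        Optional symmetric positive-semidefinite correlation matrix over
        the descriptors (order of ``means``); identity when omitted.
    target
        Optional PPI-target label attached to every row.
    seed
        Seed for the dataset's private random generator.
    """

    name: str
    n: int
    means: Mapping[str, float]
    sds: Mapping[str, float]
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    correlation: np.ndarray | None = None
    target: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if set(self.means) != set(self.sds):
            raise ValueError("means and sds must cover the same descriptors")
        for name, sd in self.sds.items():
            if sd < 0:
                raise ValueError(f"negative SD for descriptor {name!r}")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"empty bound interval for {name!r}")
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
            k = len(self.means)
            if corr.shape != (k, k):
                raise ValueError("correlation shape does not match descriptors")
            if not np.allclose(corr, corr.T):
                raise ValueError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(corr), 1.0):
                raise ValueError("correlation matrix must have unit diagonal")
            eigmin = np.linalg.eigvalsh(corr).min()
            if eigmin < -1e-10:
                raise ValueError(
                    f"correlation matrix is not positive semidefinite "
                    f"(min eigenvalue {eigmin:.3g})"
                )
            self.correlation = corr

    @property
    def descriptors(self) -> list[str]:
        return list(self.means)

    def bound(self, name: str) -> tuple[float, float]:
        return tuple(self.bounds.get(name, _UNBOUNDED))


def default_specs() -> dict[str, DatasetSpec]:
    """Built-in specs for the two PPI-inhibitor collections.

    Means and SDs are the published per-descriptor summary statistics of
    the curated iPPI-DB (n=1,650) and TIMBAL (n=1,598) inhibitor sets over
    the seven discriminative descriptors.
    """
    ippi = DatasetSpec(
        name="iPPI-DB",
        n=1650,
        means={
            "MW": 540.0,
            "AlogP": 4.61,
            "aromatic_ratio": 0.29,
            "CW2": 1.98,
            "IW4": 2.69,
            "glob": 0.16,
            "EDmin3": -2.85,
        },
        sds={
            "MW": 145.0,
            "AlogP": 1.98,
            "aromatic_ratio": 0.10,
            "CW2": 0.17,
            "IW4": 1.00,
            "glob": 0.09,
            "EDmin3": 0.19,
        },
        bounds=dict(DEFAULT_BOUNDS),
        seed=1650,
    )
    timbal = DatasetSpec(
        name="TIMBAL",
        n=1598,
        means={
            "MW": 521.0,
            "AlogP": 4.19,
            "aromatic_ratio": 0.29,
            "CW2": 1.97,
            "IW4": 2.78,
            "glob": 0.15,
            "EDmin3": -2.84,
        },
        sds={
            "MW": 179.0,
            "AlogP": 2.39,
            "aromatic_ratio": 0.12,
            "CW2": 0.20,
            "IW4": 1.16,
            "glob": 0.11,
            "EDmin3": 0.26,
        },
        bounds=dict(DEFAULT_BOUNDS),
        seed=1598,
    )
    return {s.name: s for s in (ippi, timbal)}


def illustrative_reference_specs(n: int = 1000) -> dict[str, DatasetSpec]:
    """Illustrative non-iPPI specs with shifted means.

    The reference (non-iPPI) collections' summary statistics are only shown
    graphically in the source material, so these presets are *illustrative*:
    they shift the PPI-inhibitor profile towards a smaller, less hydrophobic,
    less aromatic "conventional active" profile and must not be read as the
    real libraries' statistics.
    """
    base = default_specs()["iPPI-DB"]
    shifted = {
        "MW": (380.0, 110.0),
        "AlogP": (3.0, 1.6),
        "aromatic_ratio": (0.25, 0.10),
        "CW2": (2.15, 0.20),
        "IW4": (2.3, 1.0),
        "glob": (0.11, 0.07),
        "EDmin3": (-2.45, 0.25),
    }
    spec = DatasetSpec(
        name="illustrative_reference",
        n=n,
        means={k: v[0] for k, v in shifted.items()},
        sds={k: v[1] for k, v in shifted.items()},
        bounds=dict(base.bounds),
        seed=97,
    )
    return {spec.name: spec}


def _calibrate_truncnorm(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Parent (mu, sigma) whose (lo, hi]-truncation has the target moments.

    When the truncation mass of the naive parent N(mean, sd) is negligible
    (< 1e-9) the parameters are returned unchanged; otherwise the two moment
    equations are solved numerically.
    """
    from scipy import optimize
    from scipy.stats import norm, truncnorm

    if sd == 0.0 or (not np.isfinite(lo) and not np.isfinite(hi)):
        return mean, sd
    if norm.cdf(lo, mean, sd) + norm.sf(hi, mean, sd) < 1e-9:
        return mean, sd

    def eqs(p):
        mu, logsig = p
        sig = np.exp(logsig)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        # extreme solver excursions can make the moments degenerate (nan)
        with np.errstate(all="ignore"):
            m, v = truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
            resid = [m - mean, np.sqrt(v) - sd]
        return [r if np.isfinite(r) else 1e6 for r in resid]

    sol = optimize.root(eqs, [mean, np.log(sd)], method="hybr")
    if not sol.success or max(abs(np.asarray(eqs(sol.x)))) > 1e-8:
        # infeasible moment pair (e.g. an SD no distribution on (lo, hi) can
        # reach): fall back to plain truncation of the naive parent
        import logging

        logging.getLogger(__name__).warning(
            "no truncated normal on (%s, %s] has mean %s and sd %s; "
            "falling back to truncating N(%s, %s) (moments will deviate)",
            lo, hi, mean, sd, mean, sd,
        )
        return mean, sd
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _truncated_normal(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
) -> np.ndarray:
    """Rejection-sample a truncated Gaussian; exact for sd == 0."""
    if sd == 0.0:
        if not (lo < mean <= hi or lo <= mean < hi):
            raise ValueError(f"degenerate mean {mean} outside bounds ({lo}, {hi})")
        return np.full(n, mean)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 64))
        ok = draw[(draw > lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def generate_dataset(spec: DatasetSpec) -> pd.DataFrame:
    """Generate a descriptor table for one :class:`DatasetSpec`.

    Returns a DataFrame with ``id``, ``dataset`` (and ``target`` when the
    spec carries one) columns followed by one column per descriptor.  Output
    is bit-identical for identical spec + seed.
    """
    rng = np.random.default_rng(spec.seed)
    names = spec.descriptors
    cols: dict[str, np.ndarray] = {}
    if spec.correlation is None:
        for name in names:
            lo, hi = spec.bound(name)
            mu, sig = _calibrate_truncnorm(spec.means[name], spec.sds[name], lo, hi)
            cols[name] = _truncated_normal(rng, spec.n, mu, sig, lo, hi)
    else:
        cols_mat = _correlated_truncated(rng, spec)
        for j, name in enumerate(names):
            cols[name] = cols_mat[:, j]
    frame = pd.DataFrame(cols, columns=names)
    frame.insert(0, "dataset", spec.name)
    frame.insert(0, "id", [f"{spec.name}_{i:06d}" for i in range(spec.n)])
    if spec.target is not None:
        frame.insert(2, "target", spec.target)
    return frame


def _correlated_truncated(rng: np.random.Generator, spec: DatasetSpec) -> np.ndarray:
    """Correlated Gaussian rows with per-row rejection of bound violations."""
    names = spec.descriptors
    lo = np.array([spec.bound(n)[0] for n in names])
    hi = np.array([spec.bound(n)[1] for n in names])
    # marginal calibration; the joint row-rejection keeps it approximate
    calibrated = [
        _calibrate_truncnorm(spec.means[n], spec.sds[n], *spec.bound(n)) for n in names
    ]
    mean = np.array([c[0] for c in calibrated])
    sd = np.array([c[1] for c in calibrated])
    # eigendecomposition tolerates the PSD-but-singular case
    w, v = np.linalg.eigh(spec.correlation)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    out = np.empty((spec.n, len(names)))
    filled = 0
    while filled < spec.n:
        z = rng.standard_normal((max(spec.n - filled, 64), len(names)))
        rows = mean + (z @ root.T) * sd
        ok = rows[np.all((rows > lo) & (rows <= hi), axis=1)]
        take = min(len(ok), spec.n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def generate_collection(specs: Sequence[DatasetSpec] | Mapping[str, DatasetSpec]) -> pd.DataFrame:
    """Concatenate :func:`generate_dataset` over several specs."""
    if isinstance(specs, Mapping):
        specs = list(specs.values())
    frames = [generate_dataset(s) for s in specs]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# sub-pocket fixtures

from .pockets import DISTANCE_BINS, FEATURES, SubPocketRecord  # noqa: E402


def generate_subpockets(
    n_sub: int,
    profile: Mapping[str, float],
    seed: int,
    nb_tot_range: tuple[int, int] = (50, 500),
) -> list[SubPocketRecord]:
    """Generate toy sub-pocket records around a feature-percentage profile.

    ``profile`` maps the eight cavity-point features to percentages that
    must sum to 100.  Each record receives a random total point count, the
    profile's feature percentages jittered on the simplex, and a random
    split of each feature's percentage across the ten distance bins.
    """
    total = sum(profile.get(f, 0.0) for f in FEATURES)
    if abs(total - 100.0) > 1e-6:
        raise ValueError(f"profile percentages sum to {total}, expected 100")
    if n_sub < 1:
        raise ValueError("n_sub must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    base = np.array([profile.get(f, 0.0) for f in FEATURES], dtype=float)
    for _ in range(n_sub):
        nb_tot = int(rng.integers(nb_tot_range[0], nb_tot_range[1] + 1))
        # Dirichlet jitter around the profile, keeping zero features at zero
        pct = base.copy()
        pos = base > 0
        if pos.sum() > 1:
            pct[pos] = 100.0 * rng.dirichlet(base[pos] * 2.0)
        dist_pct: dict[tuple[str, str], float] = {}
        for f, p in zip(FEATURES, pct):
            if p == 0.0:
                split = np.zeros(len(DISTANCE_BINS))
            else:
                split = p * rng.dirichlet(np.ones(len(DISTANCE_BINS)))
            for b, v in zip(DISTANCE_BINS, split):
                dist_pct[(f, b)] = float(v)
        records.append(
            SubPocketRecord(
                nb_tot=nb_tot,
                feature_pct=dict(zip(FEATURES, map(float, pct))),
                dist_pct=dist_pct,
            )
        )
    return records


# ---------------------------------------------------------------------------
# serialization

def write_table(frame: pd.DataFrame, path) -> None:
    """Write a descriptor table as comma-separated UTF-8 text."""
    frame.to_csv(path, index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def spec_to_dict(spec: DatasetSpec) -> dict:
    d = {
        "name": spec.name,
        "n": spec.n,
        "means": dict(spec.means),
        "sds": dict(spec.sds),
        "bounds": {k: list(v) for k, v in spec.bounds.items()},
        "seed": spec.seed,
    }
    if spec.target is not None:
        d["target"] = spec.target
    if spec.correlation is not None:
        d["correlation"] = np.asarray(spec.correlation).tolist()
    return d


def write_specs(specs: Sequence[DatasetSpec], path) -> None:
    payload = [spec_to_dict(s) for s in specs]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_specs(path) -> list[DatasetSpec]:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    specs = []
    for d in payload:
        corr = d.get("correlation")
        specs.append(
            DatasetSpec(
                name=d["name"],
                n=d["n"],
                means=d["means"],
                sds=d["sds"],
                bounds={k: tuple(v) for k, v in d.get("bounds", {}).items()},
                correlation=np.asarray(corr) if corr is not None else None,
                target=d.get("target"),
                seed=d["seed"],
            )
        )
    return specs
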