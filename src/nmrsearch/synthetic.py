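"""Synthetic 13C shift sets, spectra, and retrieval benchmarks.

The generator emulates the data regime the search method is designed
for: proton-decoupled 13C spectra digitized at 0.05 ppm over 0-220 ppm,
each molecule contributing a handful of narrow singlets.  A spectrum is
the unit-height Gaussian-Lorentzian peak sum evaluated on the grid, plus
additive Gaussian baseline noise clipped at zero, max-normalized.

A benchmark couples each query spectrum with a pool entry whose shifts
are the true ones perturbed by i.i.d. Gaussian jitter — the stand-in for
chemical-shift prediction error (roughly 1-3 ppm for typical 13C
predictors) — plus independently drawn decoy molecules.

Default conditions (see docs/methods.md for rationale): per-peak FWHM
sigma uniform on [0.03, 0.10] ppm — 0.6 to 2 grid steps, the
decimation-limited width of narrow 13C singlets on a 0.05 ppm grid, and
the regime in which a threshold of 0.05 detects every peak regardless of
where its center falls between grid points — mixing lambda uniform on
[0.2, 0.8], 4-16 peaks per molecule at least 1 ppm apart, baseline noise
sd 0.01, prediction jitter sd 1 ppm.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from nmrsearch.estimation import LineshapeParams, synthesize_spectrum
from nmrsearch.shifts import ShiftSet, load_shift_table, write_shift_table
from nmrsearch.spectra import Spectrum, read_spectrum, write_spectrum

__all__ = [
    "SimConfig",
    "Benchmark",
    "simulate_shift_set",
    "simulate_spectrum",
    "make_benchmark",
    "write_benchmark",
    "load_benchmark",
]


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Generative settings for synthetic spectra and pools.

    grid_min/grid_max/grid_step : ppm window and spacing of the 13C grid.
    m_range : inclusive bounds on peaks per molecule.
    amp_range : inclusive integer multiplicity per peak; values > 1
        duplicate the shift (equivalent carbons), stacking its kernel.
    sigma_range : per-peak FWHM bounds, ppm.
    lambda_range : Gaussian-Lorentzian mixing bounds.
    noise_sd : baseline noise standard deviation (pre-normalization units).
    jitter_sd : sd of the Gaussian shift-prediction error, ppm.
    min_spacing : minimum distance between distinct shifts, ppm.
    edge_margin : keep shifts this far inside the grid window, ppm.
    """

    grid_min: float = 0.0
    grid_max: float = 220.0
    grid_step: float = 0.05
    m_range: tuple[int, int] = (4, 16)
    amp_range: tuple[int, int] = (1, 1)
    sigma_range: tuple[float, float] = (0.03, 0.10)
    lambda_range: tuple[float, float] = (0.2, 0.8)
    noise_sd: float = 0.01
    jitter_sd: float = 1.0
    min_spacing: float = 1.0
    edge_margin: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_min >= self.grid_max:
            raise ValueError("grid_min must be below grid_max")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.noise_sd < 0 or self.jitter_sd < 0:
            raise ValueError("noise_sd and jitter_sd must be nonnegative")
        if self.m_range[0] < 1 or self.m_range[0] > self.m_range[1]:
            raise ValueError("m_range must satisfy 1 <= lo <= hi")
        if self.amp_range[0] < 1 or self.amp_range[0] > self.amp_range[1]:
            raise ValueError("amp_range must satisfy 1 <= lo <= hi")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step))
        return self.grid_min + self.grid_step * np.arange(n + 1)


@dataclasses.dataclass(frozen=True)
class Benchmark:
    """Queries with known identity plus a shared candidate pool."""

    queries: tuple[Spectrum, ...]
    truth: dict[str, str]  # query label -> true molecule id
    pool: dict[str, list[ShiftSet]]
    true_shifts: dict[str, ShiftSet]  # molecule id -> generating shifts


def simulate_shift_set(
    m: int, cfg: SimConfig, rng: np.random.Generator, molecule_id: str = "sim"
) -> ShiftSet:
    """Draw m shifts uniformly inside the usable window, min_spacing apart.

    Sampling is exact (order statistics of a shrunk window plus fixed
    gaps), not rejection, so near-infeasible requests stay cheap.  Each
    shift is then repeated by an integer multiplicity from amp_range.
    """
    if not (cfg.m_range[0] <= m <= cfg.m_range[1]):
        raise ValueError(f"m={m} outside configured m_range {cfg.m_range}")
    lo = cfg.grid_min + cfg.edge_margin
    hi = cfg.grid_max - cfg.edge_margin
    span = hi - lo
    slack = span - (m - 1) * cfg.min_spacing
    if slack <= 0:
        raise ValueError(
            f"cannot place {m} shifts {cfg.min_spacing} ppm apart in {span} ppm"
        )
    base = np.sort(rng.uniform(0.0, slack, size=m))
    shifts = lo + base + cfg.min_spacing * np.arange(m)
    if cfg.amp_range != (1, 1):
        mult = rng.integers(cfg.amp_range[0], cfg.amp_range[1] + 1, size=m)
        shifts = np.repeat(shifts, mult)
    return ShiftSet(molecule_id=molecule_id, shifts=shifts, provenance="table")


def simulate_spectrum(
    shifts: ShiftSet, cfg: SimConfig, rng: np.random.Generator, label: str = ""
) -> Spectrum:
    """Synthesize a noisy, max-normalized spectrum from a shift set."""
    grid = cfg.grid()
    if np.min(shifts.shifts) < cfg.grid_min or np.max(shifts.shifts) > cfg.grid_max:
        raise ValueError("shifts fall outside the grid window")
    m = shifts.m
    params = LineshapeParams(
        mu=shifts.shifts,
        sigma=rng.uniform(*cfg.sigma_range, size=m),
        lam=rng.uniform(*cfg.lambda_range, size=m),
    )
    y = synthesize_spectrum(grid, params).intensities
    if cfg.noise_sd > 0:
        y = y + rng.normal(0.0, cfg.noise_sd, size=y.size)
    y = np.clip(y, 0.0, None)
    ymax = float(np.max(y))
    if ymax <= 0:
        raise ValueError("degenerate spectrum: all intensities zero")
    return Spectrum(grid, y / ymax, label=label or shifts.molecule_id)


def make_benchmark(
    n_queries: int, n_decoys: int, cfg: SimConfig | None = None
) -> Benchmark:
    """Build a seeded retrieval benchmark.

    For each of `n_queries` molecules a spectrum is simulated from its
    true shifts, while the pool receives those shifts perturbed by
    Gaussian jitter of sd `jitter_sd` (re-sorted ascending), emulating
    prediction error.  `n_decoys` additional molecules are independent
    draws.  Reproducible from ``cfg.seed``.
    """
    if n_queries < 1 or n_decoys < 0:
        raise ValueError("need n_queries >= 1 and n_decoys >= 0")
    cfg = cfg if cfg is not None else SimConfig()
    rng = np.random.default_rng(cfg.seed)
    queries: list[Spectrum] = []
    truth: dict[str, str] = {}
    pool: dict[str, list[ShiftSet]] = {}
    true_shifts: dict[str, ShiftSet] = {}
    for i in range(n_queries):
        mol_id = f"mol{i:04d}"
        label = f"query{i:04d}"
        m = int(rng.integers(cfg.m_range[0], cfg.m_range[1] + 1))
        true = simulate_shift_set(m, cfg, rng, molecule_id=mol_id)
        queries.append(simulate_spectrum(true, cfg, rng, label=label))
        jittered = true.shifts + rng.normal(0.0, cfg.jitter_sd, size=true.m)
        pool[mol_id] = [ShiftSet(mol_id, jittered, provenance="table")]
        true_shifts[mol_id] = true
        truth[label] = mol_id
    for i in range(n_decoys):
        mol_id = f"decoy{i:04d}"
        m = int(rng.integers(cfg.m_range[0], cfg.m_range[1] + 1))
        decoy = simulate_shift_set(m, cfg, rng, molecule_id=mol_id)
        jittered = decoy.shifts + rng.normal(0.0, cfg.jitter_sd, size=decoy.m)
        pool[mol_id] = [ShiftSet(mol_id, jittered, provenance="table")]
    return Benchmark(
        queries=tuple(queries), truth=truth, pool=pool, true_shifts=true_shifts
    )


def write_benchmark(bench: Benchmark, out_dir: str | Path) -> None:
    """Write a benchmark in the package's standard text formats.

    Layout: one spectrum file per query (``<label>.tsv``), a long-format
    shift table ``shifts.tsv``, a pool listing ``pool.tsv``, and a truth
    manifest ``truth.tsv`` mapping query labels to molecule ids.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for spec in bench.queries:
        write_spectrum(spec, out / f"{spec.label}.tsv")
    write_shift_table(bench.pool, out / "shifts.tsv")
    with (out / "pool.tsv").open("w") as fh:
        fh.write("molecule_id\n")
        for mol_id in bench.pool:
            fh.write(f"{mol_id}\n")
    with (out / "truth.tsv").open("w") as fh:
        fh.write("query_label\ttrue_molecule_id\n")
        for label, mol_id in bench.truth.items():
            fh.write(f"{label}\t{mol_id}\n")


def load_benchmark(bench_dir: str | Path) -> Benchmark:
    """Load a benchmark directory written by :func:`write_benchmark`."""
    bench = Path(bench_dir)
    truth: dict[str, str] = {}
    with (bench / "truth.tsv").open() as fh:
        next(fh)  # header
        for line in fh:
            if line.strip():
                label, mol_id = line.split()
                truth[label] = mol_id
    queries = tuple(
        read_spectrum(bench / f"{label}.tsv", label=label) for label in truth
    )
    pool = load_shift_table(bench / "shifts.tsv")
    return Benchmark(queries=queries, truth=truth, pool=pool, true_shifts={})
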