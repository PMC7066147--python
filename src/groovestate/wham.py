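"""Umbrella-sampling analysis on a periodic dihedral coordinate.

Reconstructs the potential of mean force (PMF) along a side-chain torsion
from biased window time series via the weighted histogram analysis method
(WHAM), with the error and convergence diagnostics used for dihedral
umbrella sampling: integrated autocorrelation times, block standard
errors, and cumulative-PMF convergence checks.

Conventions
-----------
* The reaction coordinate is an angle in degrees, treated on the periodic
  interval (-180, 180].  Window centers outside that interval (the
  A2 Tyr116 protocol runs -210 deg to -50 deg) are retained as labels and
  wrapped for binning.
* The bias is the quadratic penalty U(xi) = k * dmin(xi, center)**2 with
  dmin the minimum-image angular difference, i.e. **no 1/2 factor**; k is
  in kcal mol-1 deg-2 (the Tyr116 protocol uses k = 0.015).  Set
  ``bias_convention="half"`` in :class:`WhamConfig` for the U = k/2 * d**2
  convention.
* k_B = 0.0019872041 kcal mol-1 K-1; default temperature 300 K.

The model-style entry point is :class:`UmbrellaSampling`, whose ``fit()``
returns a :class:`PMFResult`; the underlying functions (`wham_pmf`,
`pmf_diagnostics`, `autocorr_time`, ...) are usable directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import RotamerBins, classify_rotamer, wrap_angle

__all__ = [
    "KB_KCAL",
    "UmbrellaWindowSeries",
    "WhamConfig",
    "PMFProfile",
    "WhamConvergenceError",
    "DegenerateSeriesError",
    "make_windows",
    "bias_energy",
    "wham_pmf",
    "well_sampled_mask",
    "autocorr_time",
    "PmfDiagnostics",
    "pmf_diagnostics",
    "ConditionalDistributions",
    "conditional_dihedral_distribution",
    "UmbrellaSampling",
    "PMFResult",
    "read_window_file",
    "write_window_file",
    "read_manifest",
]

#: Boltzmann constant, kcal mol-1 K-1.
KB_KCAL = 0.0019872041


class WhamConvergenceError(RuntimeError):
    """WHAM self-consistency iteration did not reach tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class DegenerateSeriesError(ValueError):
    """Time series unusable for the requested statistic (e.g. constant)."""


@dataclass
class UmbrellaWindowSeries:
    """One umbrella window: bias parameters plus the sampled dihedrals."""

    center: float                      # deg (label; may lie outside (-180, 180])
    force_constant: float              # kcal mol-1 deg-2
    samples: np.ndarray                # deg
    sampling_interval: float = 1.0     # arbitrary time units per sample
    label: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.force_constant <= 0:
            raise ValueError("force constant must be positive")
        if self.samples.size < 1:
            raise ValueError("window needs at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window samples must be finite")
        if self.sampling_interval <= 0:
            raise ValueError("sampling interval must be positive")

    def restricted(self, start: int, stop: int) -> "UmbrellaWindowSeries":
        return replace(self, samples=self.samples[start:stop])


@dataclass(frozen=True)
class WhamConfig:
    """Solver settings for the WHAM reconstruction."""

    temperature: float = 300.0        # K
    bin_width: float = 2.0            # deg
    tolerance: float = 1e-8           # kcal/mol, on window free-energy constants
    max_iterations: int = 100_000
    boltzmann: float = KB_KCAL        # kcal mol-1 K-1
    bias_convention: str = "full"     # "full": U = k d^2;  "half": U = k/2 d^2

    def __post_init__(self):
        for name in ("temperature", "bin_width", "tolerance", "boltzmann"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.bias_convention not in ("full", "half"):
            raise ValueError("bias_convention must be 'full' or 'half'")

    @property
    def kt(self) -> float:
        return self.boltzmann * self.temperature


@dataclass
class PMFProfile:
    """Free-energy profile on a periodic dihedral grid.

    ``free_energy`` is NaN on bins with zero total counts (never
    interpolated); over sampled bins the minimum is normalized to 0.
    """

    grid: np.ndarray                   # bin centers, deg, strictly increasing
    free_energy: np.ndarray            # kcal/mol
    temperature: float                 # K
    stderr: np.ndarray | None = None   # kcal/mol
    counts: np.ndarray | None = None   # total samples per bin
    n_iterations: int | None = None
    residual: float | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if self.grid.shape != self.free_energy.shape:
            raise ValueError("grid/free_energy shape mismatch")

    @property
    def sampled(self) -> np.ndarray:
        """Boolean mask of bins that carry a defined free energy."""
        return np.isfinite(self.free_energy)

    def barrier_height(self) -> float:
        """Max minus min free energy over sampled bins, kcal/mol."""
        g = self.free_energy[self.sampled]
        return float(g.max() - g.min())

    def value_at(self, angle: float) -> float:
        """Free energy of the bin containing ``angle`` (deg)."""
        idx = int(np.argmin(np.abs(wrap_angle(self.grid - angle))))
        return float(self.free_energy[idx])


def make_windows(lo: float, hi: float, step: float) -> list[float]:
    """Evenly spaced umbrella window centers, ``lo`` to ``hi`` inclusive.

    Centers are labels: no periodic deduplication is applied, so the
    Tyr116 protocol ``make_windows(-210, -50, 10)`` yields 17 centers.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if hi < lo:
        raise ValueError("hi must be >= lo")
    n_steps = (hi - lo) / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"range ({lo}, {hi}) not divisible by step {step}")
    n = int(round(n_steps)) + 1
    return [lo + i * step for i in range(n)]


def bias_energy(xi, center, k, convention: str = "full"):
    """Quadratic umbrella penalty (kcal/mol) at dihedral ``xi`` (deg).

    The angular difference is wrapped to the minimum image, so the bias is
    periodic: a window centered at -210 deg restrains samples near +150 deg
    equally.  Symmetric in (xi, center).
    """
    if np.any(np.asarray(k) <= 0):
        raise ValueError("force constant must be positive")
    delta = wrap_angle(np.asarray(xi, dtype=float) - np.asarray(center, dtype=float))
    u = k * np.asarray(delta) ** 2
    if convention == "half":
        u = 0.5 * u
    out = np.asarray(u, dtype=float)
    return float(out) if out.ndim == 0 else out


def _grid(bin_width: float) -> tuple[np.ndarray, int]:
    n_bins = 360.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin width must divide 360 deg")
    n_bins = int(round(n_bins))
    centers = -180.0 + bin_width * (np.arange(n_bins) + 0.5)
    return centers, n_bins


def _bin_indices(samples: np.ndarray, bin_width: float, n_bins: int) -> np.ndarray:
    wrapped = wrap_angle(samples)
    idx = np.floor((wrapped + 180.0) / bin_width).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def wham_pmf(windows: Sequence[UmbrellaWindowSeries],
             config: WhamConfig | None = None) -> PMFProfile:
    """Self-consistent WHAM reconstruction of the PMF from biased windows.

    Window histograms are combined on a periodic grid; the per-window free
    energy constants f_i are iterated (deterministic all-zero start) until
    their maximum change per sweep falls below ``config.tolerance``.  The
    unbiased probability is converted to W(xi) = -k_B T ln p, minimum over
    sampled bins normalized to 0; empty bins are NaN and flagged via
    ``PMFProfile.sampled``.
    """
    if len(windows) == 0:
        raise ValueError("need at least one umbrella window")
    config = config or WhamConfig()
    kt = config.kt
    centers, n_bins = _grid(config.bin_width)

    n_w = len(windows)
    counts = np.zeros((n_w, n_bins))
    n_samples = np.zeros(n_w)
    for i, w in enumerate(windows):
        idx = _bin_indices(w.samples, config.bin_width, n_bins)
        counts[i] = np.bincount(idx, minlength=n_bins)
        n_samples[i] = w.samples.size

    _warn_on_gaps(windows, counts)

    with np.errstate(under="ignore"):
        bias = np.stack([
            bias_energy(centers, w.center, w.force_constant,
                        config.bias_convention)
            for w in windows
        ])                                          # (W, B)
        boltz = np.exp(-bias / kt)                  # underflows to 0 far away

        total_counts = counts.sum(axis=0)
        f = np.zeros(n_w)
        residual = np.inf
        for iteration in range(1, config.max_iterations + 1):
            denom = (n_samples[:, None] * np.exp(f / kt)[:, None] * boltz).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(denom > 0, total_counts / denom, 0.0)
            z = (p[None, :] * boltz).sum(axis=1)
            if np.any(z <= 0):
                raise WhamConvergenceError(
                    "a window has zero overlap with the sampled region",
                    residual=float("inf"))
            f_new = -kt * np.log(z)
            f_new -= f_new[0]
            residual = float(np.max(np.abs(f_new - f)))
            f = f_new
            if residual < config.tolerance:
                break
        else:
            raise WhamConvergenceError(
                f"WHAM did not converge in {config.max_iterations} iterations "
                f"(last residual {residual:.3e} kcal/mol)", residual=residual)

    p_sum = p.sum()
    p = p / p_sum
    with np.errstate(divide="ignore"):
        g = np.where(p > 0, -kt * np.log(np.where(p > 0, p, 1.0)), np.nan)
    g -= np.nanmin(g)
    return PMFProfile(grid=centers, free_energy=g, temperature=config.temperature,
                      counts=total_counts, n_iterations=iteration,
                      residual=residual)


def _warn_on_gaps(windows, counts) -> None:
    """Warn when adjacent windows (by center) share no occupied bins."""
    order = np.argsort([w.center for w in windows])
    occupied = counts > 0
    for a, b in zip(order[:-1], order[1:]):
        if not np.any(occupied[a] & occupied[b]):
            warnings.warn(
                f"umbrella windows at {windows[a].center} deg and "
                f"{windows[b].center} deg share no occupied bins; the PMF "
                "offset between them is unconstrained", stacklevel=3)


def well_sampled_mask(windows: Sequence[UmbrellaWindowSeries],
                      config: WhamConfig | None = None,
                      min_windows: int = 2) -> np.ndarray:
    """Bins occupied by at least ``min_windows`` windows.

    Bins visited by a single window at the edge of the sampled range carry
    poorly constrained offsets; error and convergence statements are made
    over this mask.
    """
    config = config or WhamConfig()
    _, n_bins = _grid(config.bin_width)
    occupancy = np.zeros(n_bins)
    for w in windows:
        idx = _bin_indices(w.samples, config.bin_width, n_bins)
        occupancy += np.bincount(idx, minlength=n_bins) > 0
    return occupancy >= min_windows


def autocorr_time(samples, max_lag: int | None = None) -> float:
    """Integrated autocorrelation time tau = 1 + 2 * sum rho_k.

    The sum over the normalized autocorrelation function is truncated at the
    first negative rho_k (initial-positive-sequence style cutoff).  Returned
    in the series' sampling-interval units; accepts a raw array (interval 1)
    or an :class:`UmbrellaWindowSeries`.
    """
    interval = 1.0
    if isinstance(samples, UmbrellaWindowSeries):
        interval = samples.sampling_interval
        samples = samples.samples
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 10:
        raise DegenerateSeriesError("need at least 10 samples")
    x = x - x.mean()
    var = np.dot(x, x) / x.size
    if var <= 0:
        raise DegenerateSeriesError("constant series has no autocorrelation time")
    n = x.size
    # FFT autocovariance
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[:n] / n
    rho = acov / acov[0]
    if max_lag is None:
        max_lag = n - 1
    tau = 1.0
    for k in range(1, min(max_lag, n - 1) + 1):
        if rho[k] < 0:
            break
        tau += 2.0 * rho[k]
    return float(tau * interval)


@dataclass
class PmfDiagnostics:
    """Block-error and convergence diagnostics for a WHAM profile."""

    grid: np.ndarray
    stderr: np.ndarray                       # kcal/mol per bin (NaN if <2 blocks)
    block_profiles: list[PMFProfile]
    cumulative_profiles: list[PMFProfile]
    fractions: tuple[float, ...]
    n_blocks: int

    def max_deviation_from_final(self, mask: np.ndarray | None = None,
                                 ) -> list[float]:
        """Max |cumulative PMF - full PMF| per fraction.

        Taken over bins finite in both profiles, optionally restricted to
        a ``mask`` (e.g. :func:`well_sampled_mask`).
        """
        final = self.cumulative_profiles[-1].free_energy
        out = []
        for prof in self.cumulative_profiles:
            both = np.isfinite(final) & np.isfinite(prof.free_energy)
            if mask is not None:
                both &= mask
            out.append(float(np.max(np.abs(prof.free_energy[both] - final[both]))))
        return out


def pmf_diagnostics(windows: Sequence[UmbrellaWindowSeries],
                    config: WhamConfig | None = None,
                    n_blocks: int = 10,
                    fractions: Sequence[float] = (0.4, 0.6, 0.8, 1.0),
                    ) -> PmfDiagnostics:
    """Per-bin block standard errors and cumulative-PMF convergence series.

    Each window's samples are split into ``n_blocks`` contiguous
    equal-length blocks (intervals in sampling order, mirroring time
    intervals).  A full WHAM solve is run per block; every block profile is
    min-normalized before aggregation, and the per-bin standard error is
    the block standard deviation divided by sqrt(n_blocks).  Cumulative
    profiles are WHAM solves on growing sample prefixes.
    """
    config = config or WhamConfig()
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    for w in windows:
        if w.samples.size < n_blocks:
            raise ValueError(
                f"window at {w.center} deg has {w.samples.size} samples; "
                f"fewer than n_blocks={n_blocks}")
    if not fractions or any(not (0 < fr <= 1) for fr in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    fractions = tuple(sorted(fractions))

    block_profiles = []
    for j in range(n_blocks):
        blocks = []
        for w in windows:
            n = w.samples.size
            start, stop = (j * n) // n_blocks, ((j + 1) * n) // n_blocks
            blocks.append(w.restricted(start, stop))
        block_profiles.append(wham_pmf(blocks, config))

    g = np.stack([prof.free_energy for prof in block_profiles])  # (J, B)
    defined = np.isfinite(g).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stderr = np.nanstd(g, axis=0, ddof=1) / np.sqrt(n_blocks)
    stderr[defined < 2] = np.nan

    cumulative = []
    for fr in fractions:
        prefix = [w.restricted(0, max(1, int(round(fr * w.samples.size))))
                  for w in windows]
        cumulative.append(wham_pmf(prefix, config))

    return PmfDiagnostics(grid=block_profiles[0].grid, stderr=stderr,
                          block_profiles=block_profiles,
                          cumulative_profiles=cumulative,
                          fractions=fractions, n_blocks=n_blocks)


@dataclass
class ConditionalDistributions:
    """Secondary-dihedral histograms conditioned on a primary rotamer regime."""

    grid: np.ndarray
    regimes: tuple[str, str]
    histograms: tuple[np.ndarray | None, np.ndarray | None]  # each sums to 1
    counts: tuple[int, int]

    @property
    def empty(self) -> tuple[bool, bool]:
        return tuple(c == 0 for c in self.counts)

    def total_variation(self) -> float:
        """TV distance between the two conditionals (requires both non-empty)."""
        a, b = self.histograms
        if a is None or b is None:
            raise ValueError("a conditional is empty")
        return float(0.5 * np.abs(a - b).sum())


def conditional_dihedral_distribution(primary, secondary,
                                      bins: RotamerBins | None = None,
                                      regime_a: str = "trans",
                                      regime_b: str = "gauche_minus",
                                      n_bins: int = 72,
                                      ) -> ConditionalDistributions:
    """Histograms of a secondary dihedral split by the primary's regime.

    Mirrors conditioning a neighboring side chain's dihedral distribution
    on whether Tyr116 chi1 is trans (locked) or -gauche (unlocked).  Each
    histogram is normalized to sum to 1; a regime with zero members is
    flagged empty (``None`` histogram) rather than raising.
    """
    primary = np.asarray(primary, dtype=float).ravel()
    secondary = np.asarray(secondary, dtype=float).ravel()
    if primary.size != secondary.size:
        raise ValueError("primary and secondary series must have equal length")
    bins = bins or RotamerBins()
    regimes = np.array([classify_rotamer(x, bins) for x in primary])
    width = 360.0 / n_bins
    centers = -180.0 + width * (np.arange(n_bins) + 0.5)

    hists, counts = [], []
    for regime in (regime_a, regime_b):
        sel = secondary[regimes == regime]
        counts.append(int(sel.size))
        if sel.size == 0:
            hists.append(None)
            continue
        idx = _bin_indices(sel, width, n_bins)
        h = np.bincount(idx, minlength=n_bins).astype(float)
        hists.append(h / h.sum())
    return ConditionalDistributions(grid=centers, regimes=(regime_a, regime_b),
                                    histograms=tuple(hists),
                                    counts=tuple(counts))


# ---------------------------------------------------------------------------
# Model-style interface


class UmbrellaSampling:
    """Umbrella-sampling free-energy model over one periodic dihedral.

    Parameters
    ----------
    windows
        The biased window series (centers, force constants, samples).
    temperature, bin_width, tolerance, max_iterations, bias_convention
        Forwarded to :class:`WhamConfig`.

    ``fit()`` runs the WHAM reconstruction (optionally with block-error and
    cumulative-convergence diagnostics) and returns a :class:`PMFResult`.
    """

    def __init__(self, windows: Sequence[UmbrellaWindowSeries], *,
                 temperature: float = 300.0, bin_width: float = 2.0,
                 tolerance: float = 1e-8, max_iterations: int = 100_000,
                 bias_convention: str = "full"):
        self.windows = list(windows)
        self.config = WhamConfig(temperature=temperature, bin_width=bin_width,
                                 tolerance=tolerance,
                                 max_iterations=max_iterations,
                                 bias_convention=bias_convention)

    @classmethod
    def from_manifest(cls, manifest_path, **kwargs) -> "UmbrellaSampling":
        return cls(read_manifest(manifest_path), **kwargs)

    def fit(self, diagnostics: bool = True, n_blocks: int = 10,
            fractions: Sequence[float] = (0.4, 0.6, 0.8, 1.0)) -> "PMFResult":
        profile = wham_pmf(self.windows, self.config)
        diag = None
        if diagnostics:
            diag = pmf_diagnostics(self.windows, self.config,
                                   n_blocks=n_blocks, fractions=fractions)
            profile.stderr = diag.stderr
        taus = [autocorr_time(w) for w in self.windows
                if w.samples.size >= 10 and np.std(w.samples) > 0]
        return PMFResult(model=self, profile=profile, diagnostics=diag,
                         autocorr_times=taus)


@dataclass
class PMFResult:
    """Fitted PMF with uncertainties and convergence diagnostics."""

    model: UmbrellaSampling
    profile: PMFProfile
    diagnostics: PmfDiagnostics | None
    autocorr_times: list[float]

    def barrier_height(self) -> float:
        return self.profile.barrier_height()

    def minima(self, n: int = 2, half_window: int = 3,
               ) -> list[tuple[float, float]]:
        """Up to ``n`` local minima of the profile as (angle deg, kcal/mol).

        A bin is a minimum when it is the lowest of its ±``half_window``
        periodic neighbourhood, which suppresses bin-level noise dips.
        """
        g = self.profile.free_energy
        grid = self.profile.grid
        n_bins = g.size
        found = []
        for i in range(n_bins):
            if not np.isfinite(g[i]):
                continue
            hood = [g[(i + d) % n_bins] for d in range(-half_window,
                                                       half_window + 1)
                    if d != 0]
            if not all(np.isfinite(h) for h in hood):
                continue
            before = [g[(i + d) % n_bins] for d in range(-half_window, 0)]
            after = [g[(i + d) % n_bins] for d in range(1, half_window + 1)]
            if all(g[i] <= h for h in before) and all(g[i] < h for h in after):
                found.append((float(grid[i]), float(g[i])))
        found.sort(key=lambda t: t[1])
        return found[:n]

    def summary(self) -> str:
        prof = self.profile
        lines = [
            "Umbrella-sampling PMF (WHAM)",
            "=" * 34,
            f"windows:           {len(self.model.windows)}",
            f"temperature:       {prof.temperature:g} K",
            f"bin width:         {self.model.config.bin_width:g} deg",
            f"iterations:        {prof.n_iterations}",
            f"final residual:    {prof.residual:.2e} kcal/mol",
            f"sampled bins:      {int(prof.sampled.sum())}/{prof.grid.size}",
            f"barrier height:    {self.barrier_height():.3f} kcal/mol",
        ]
        if self.autocorr_times:
            lines.append(
                f"autocorr time:     max {max(self.autocorr_times):.1f} "
                "sampling intervals")
        for angle, g in self.minima():
            lines.append(f"local minimum:     {angle:+8.1f} deg  {g:.3f} kcal/mol")
        if self.diagnostics is not None:
            mask = well_sampled_mask(self.model.windows, self.model.config)
            dev = self.diagnostics.max_deviation_from_final(mask=mask)
            frs = self.diagnostics.fractions
            lines.append("cumulative-PMF max deviation from full sampling:")
            for fr, d in zip(frs, dev):
                lines.append(f"  {int(fr * 100):3d}% of samples: {d:.4f} kcal/mol")
        return "\n".join(lines)

    def to_dataframe(self):
        import pandas as pd
        prof = self.profile
        return pd.DataFrame({
            "angle_deg": prof.grid,
            "free_energy_kcal_mol": prof.free_energy,
            "stderr_kcal_mol": (prof.stderr if prof.stderr is not None
                                else np.full(prof.grid.size, np.nan)),
            "counts": prof.counts,
        })

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        prof = self.profile
        ax.plot(prof.grid, prof.free_energy, lw=1.5, color="k")
        if prof.stderr is not None:
            ok = np.isfinite(prof.free_energy) & np.isfinite(prof.stderr)
            ax.fill_between(prof.grid[ok],
                            prof.free_energy[ok] - prof.stderr[ok],
                            prof.free_energy[ok] + prof.stderr[ok],
                            alpha=0.3, color="gray")
        ax.set_xlabel("dihedral (deg)")
        ax.set_ylabel("free energy (kcal/mol)")
        return ax


# ---------------------------------------------------------------------------
# Plain-text window files


def write_window_file(series: UmbrellaWindowSeries, path) -> None:
    """Two-column (time, dihedral deg) text file with a ``#`` metadata header."""
    path = Path(path)
    t = np.arange(series.samples.size) * series.sampling_interval
    with path.open("w") as fh:
        fh.write(f"# center = {series.center}\n")
        fh.write(f"# force_constant = {series.force_constant}\n")
        fh.write(f"# sampling_interval = {series.sampling_interval}\n")
        for ti, xi in zip(t, series.samples):
            fh.write(f"{ti:.6g}\t{xi:.6f}\n")


def read_window_file(path) -> UmbrellaWindowSeries:
    """Read one window file written by :func:`write_window_file`."""
    path = Path(path)
    meta: dict[str, float] = {}
    values = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, val = (s.strip() for s in body.split("=", 1))
                try:
                    meta[key] = float(val)
                except ValueError:
                    pass
            continue
        parts = line.split()
        values.append(float(parts[-1]))
    if "center" not in meta or "force_constant" not in meta:
        raise ValueError(f"{path}: missing '# center =' / '# force_constant =' header")
    return UmbrellaWindowSeries(center=meta["center"],
                                force_constant=meta["force_constant"],
                                samples=np.asarray(values),
                                sampling_interval=meta.get("sampling_interval", 1.0),
                                label=path.stem)


def read_manifest(path) -> list[UmbrellaWindowSeries]:
    """Manifest: TSV lines ``path<TAB>center<TAB>force_constant`` (or just paths).

    Relative window paths are resolved against the manifest's directory.
    """
    path = Path(path)
    out = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        wpath = Path(parts[0])
        if not wpath.is_absolute():
            wpath = path.parent / wpath
        series = read_window_file(wpath)
        if len(parts) >= 3:
            series = replace(series, center=float(parts[1]),
                             force_constant=float(parts[2]))
        out.append(series)
    if not out:
        raise ValueError(f"manifest {path} lists no windows")
    return out
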