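"""Weighted histogram analysis method (WHAM) for 1D umbrella sampling.

Reconstructs a potential of mean force (PMF) along a scalar reaction
coordinate -- here, typically the Cα--Cα distance between the two
membrane-proximal Thr residues of a receptor dimer -- from a set of
harmonically biased sampling windows.  The umbrella protocol mirrored by the
synthetic generator uses 20 windows spaced 1 Å apart with a bias force
constant of 1 kcal·mol⁻¹·Å⁻².

The estimator solves the standard self-consistent WHAM equations: with
per-window bias energies :math:`w_i(x)` and sample counts :math:`n_{ib}` in
bin *b*,

.. math::

    P(x_b) = \\frac{\\sum_i n_{ib}}
                  {\\sum_i N_i \\exp[\\beta(f_i - w_i(x_b))]},
    \\qquad
    e^{-\\beta f_i} = \\sum_b P(x_b)\\, e^{-\\beta w_i(x_b)},

iterated until the per-window free-energy constants :math:`f_i` stop
changing, then :math:`F(x_b) = -k_BT \\ln P(x_b)` shifted so its minimum is
zero.  Energies are handled internally in kJ·mol⁻¹; kcal inputs are
converted at exactly 4.184.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import constants

__all__ = [
    "KCAL_TO_KJ",
    "UmbrellaWindow",
    "PMFProfile",
    "WhamError",
    "kBT",
    "wham",
    "pmf_delta",
    "read_window_file",
    "read_manifest",
]

#: thermochemical calorie: exact
KCAL_TO_KJ = 4.184


class WhamError(ValueError):
    """Contract violation in the free-energy reconstruction."""


def kBT(temperature: float) -> float:
    """Thermal energy k_B·T in kJ·mol⁻¹ (Boltzmann constant times Avogadro
    number times temperature, i.e. the molar gas constant R·T)."""
    if not temperature > 0:
        raise WhamError(f"temperature must be positive, got {temperature}")
    return constants.R * temperature / 1000.0


@dataclass
class UmbrellaWindow:
    """One biased sampling window.

    ``center`` and ``samples`` are reaction-coordinate values in Å;
    ``force_constant`` is the harmonic bias stiffness, interpreted in the
    declared ``unit`` and converted to the internal kJ·mol⁻¹·Å⁻² canonical
    form on construction.  ``unbiased=True`` marks an unbiased window
    (bias energy identically zero), used for flat-potential checks.
    """

    center: float
    force_constant: float
    samples: np.ndarray
    unit: str = "kJ_per_mol_A2"
    unbiased: bool = False

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size < 1:
            raise WhamError("window has no samples")
        if not np.isfinite(self.samples).all():
            raise WhamError("window samples contain non-finite values")
        if self.unit == "kcal_per_mol_A2":
            self.force_constant = float(self.force_constant) * KCAL_TO_KJ
            self.unit = "kJ_per_mol_A2"
        elif self.unit != "kJ_per_mol_A2":
            raise WhamError(f"unknown force-constant unit {self.unit!r}")
        if not self.unbiased and not self.force_constant > 0:
            raise WhamError("force_constant must be > 0 (or set unbiased=True)")

    def bias_energy(self, x: np.ndarray) -> np.ndarray:
        """Harmonic bias w(x) = k/2 (x - center)², kJ·mol⁻¹."""
        if self.unbiased:
            return np.zeros_like(np.asarray(x, dtype=float))
        return 0.5 * self.force_constant * (np.asarray(x, dtype=float) - self.center) ** 2


@dataclass
class PMFProfile:
    """Reconstructed potential of mean force on a uniform grid.

    ``free_energy`` is in kJ·mol⁻¹ with its minimum shifted to zero; bins
    with no samples carry NaN.  ``window_offsets`` are the converged
    per-window free-energy constants f_i (gauge: first window = 0).
    """

    bin_centers: np.ndarray
    free_energy: np.ndarray
    sample_counts: np.ndarray
    converged: bool
    iterations: int
    temperature: float
    bin_width: float
    window_offsets: np.ndarray = field(default_factory=lambda: np.zeros(0))
    gaps: tuple[tuple[float, float], ...] = ()
    n_outside: int = 0

    def value_at(self, x: float) -> float:
        """Free energy at ``x`` by linear interpolation between bin centers."""
        ok = np.isfinite(self.free_energy)
        lo, hi = self.bin_centers[ok][0], self.bin_centers[ok][-1]
        if not lo <= x <= hi:
            raise WhamError(f"coordinate {x} outside profile range [{lo:.3f}, {hi:.3f}]")
        return float(np.interp(x, self.bin_centers[ok], self.free_energy[ok]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center_A": self.bin_centers,
                "free_energy_kJ_mol": self.free_energy,
                "count": self.sample_counts,
            }
        )

    def summary(self) -> str:
        ok = np.isfinite(self.free_energy)
        lines = [
            "Potential of mean force (WHAM)",
            f"  bins: {len(self.bin_centers)} x {self.bin_width:g} A, "
            f"range [{self.bin_centers[0]:.3f}, {self.bin_centers[-1]:.3f}] A",
            f"  temperature: {self.temperature:g} K (kBT = {kBT(self.temperature):.3f} kJ/mol)",
            f"  converged: {self.converged} after {self.iterations} iterations",
            f"  max free energy: {np.nanmax(self.free_energy):.3f} kJ/mol "
            f"at {self.bin_centers[ok][np.nanargmax(self.free_energy[ok])]:.2f} A",
            f"  minimum at {self.bin_centers[ok][np.nanargmin(self.free_energy[ok])]:.2f} A",
        ]
        if self.gaps:
            lines.append(f"  WARNING: empty-bin gaps at {self.gaps}")
        if self.n_outside:
            lines.append(f"  samples outside binning range: {self.n_outside}")
        return "\n".join(lines)


def wham(
    windows: Sequence[UmbrellaWindow],
    temperature: float = 300.0,
    bin_width: float = 0.1,
    tolerance: float = 1e-6,
    max_iterations: int = 100_000,
) -> PMFProfile:
    """Self-consistent WHAM over a set of umbrella windows.

    Iterates the coupled equations until the maximum change in any
    per-window free-energy constant is below ``tolerance`` (kJ·mol⁻¹).
    Non-convergence is reported via ``converged=False``, never silently.
    Empty interior bins (sampling gaps between windows) are reported in
    ``gaps``.
    """
    if not windows:
        raise WhamError("need at least one umbrella window")
    kt = kBT(temperature)
    beta = 1.0 / kt

    all_samples = np.concatenate([w.samples for w in windows])
    lo = np.floor(all_samples.min() / bin_width) * bin_width
    hi = np.ceil(all_samples.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_bins = len(centers)

    counts = np.zeros((len(windows), n_bins))
    n_outside = 0
    for i, w in enumerate(windows):
        # half-open [lo, hi) bins; the last edge is inclusive by np.histogram
        counts[i], _ = np.histogram(w.samples, bins=edges)
        n_outside += int(w.samples.size - counts[i].sum())
    h = counts.sum(axis=0)  # total counts per bin
    n_i = counts.sum(axis=1)  # samples per window actually binned

    bias = np.stack([w.bias_energy(centers) for w in windows])  # (W, B)
    boltz = np.exp(-beta * bias)

    f = np.zeros(len(windows))
    converged = False
    iterations = 0
    nonempty = h > 0
    for iterations in range(1, max_iterations + 1):
        denom = (n_i[:, None] * np.exp(beta * f)[:, None] * boltz).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, h / denom, 0.0)
        z = boltz @ p  # per-window partition sums
        f_new = -kt * np.log(z)
        f_new -= f_new[0]  # fix the additive gauge
        delta = np.abs(f_new - f).max()
        f = f_new
        if delta < tolerance:
            converged = True
            break

    denom = (n_i[:, None] * np.exp(beta * f)[:, None] * boltz).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom > 0, h / denom, np.nan)
        free = -kt * np.log(p)
    free[~nonempty] = np.nan
    free -= np.nanmin(free)

    gaps: list[tuple[float, float]] = []
    idx = np.flatnonzero(nonempty)
    if idx.size:
        inside = np.arange(idx[0], idx[-1] + 1)
        run_start = None
        for b in inside:
            if not nonempty[b] and run_start is None:
                run_start = b
            elif nonempty[b] and run_start is not None:
                gaps.append((float(centers[run_start]), float(centers[b - 1])))
                run_start = None

    return PMFProfile(
        bin_centers=centers,
        free_energy=free,
        sample_counts=h,
        converged=converged,
        iterations=iterations,
        temperature=temperature,
        bin_width=bin_width,
        window_offsets=f,
        gaps=tuple(gaps),
        n_outside=n_outside,
    )


def pmf_delta(profile: PMFProfile, x_from: float, x_to: float) -> float:
    """Free-energy difference F(x_to) - F(x_from), kJ·mol⁻¹ (interpolated)."""
    return profile.value_at(x_to) - profile.value_at(x_from)


# ---------------------------------------------------------------------------
# plain-text window files (de-facto WHAM tool convention)
# ---------------------------------------------------------------------------


def read_window_file(path) -> UmbrellaWindow:
    """Read one window: ``# center=... k=... unit=...`` header, one sample/line."""
    path = Path(path)
    meta: dict[str, str] = {}
    samples: list[float] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for token in line[1:].split():
                if "=" in token:
                    key, val = token.split("=", 1)
                    meta[key.strip()] = val.strip()
        else:
            samples.append(float(line.split()[0]))
    if "center" not in meta or "k" not in meta:
        raise WhamError(f"{path}: header must declare center= and k=")
    unit = meta.get("unit", "kJ_per_mol_A2")
    unit = {"kcal": "kcal_per_mol_A2", "kJ": "kJ_per_mol_A2"}.get(unit, unit)
    k = float(meta["k"])
    return UmbrellaWindow(
        center=float(meta["center"]),
        force_constant=k,
        samples=np.array(samples),
        unit=unit,
        unbiased=k == 0,
    )


def read_manifest(path) -> list[UmbrellaWindow]:
    """Read a manifest (one window-file path per line, relative to it)."""
    path = Path(path)
    windows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        windows.append(read_window_file(path.parent / line))
    if not windows:
        raise WhamError(f"{path}: empty manifest")
    return windows
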