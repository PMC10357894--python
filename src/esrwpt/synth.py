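"""Seeded first-order simulator of derivative-mode cw ESR spectra.

Spectra are built as stick patterns from the first-order hyperfine rule —
``n`` equivalent spin-``I`` nuclei split a line into ``2 n I + 1`` components
with multinomial intensities — convolved with the first derivative of a
Gaussian or Lorentzian lineshape, summed over weighted spin systems, with
white Gaussian noise from a seeded generator.

This is deliberately *not* a physics-grade simulator: it is isotropic and
region-wise (a "g-parallel manifold" is just another spin system placed at
its resonance field), with no powder averaging, no second-order shifts and
no relaxation or passage effects.  That is exactly the regime in which the
wavelet extraction operates — locally regular multiplets around a resonance
field — and it provides machine-readable ground truth for every test.

All fields, couplings and linewidths are in gauss; linewidths are
peak-to-peak widths of the derivative lineshape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .peaks import G_PER_GHZ
from .spectra import Spectrum

__all__ = [
    "SpinSystemSpec",
    "SimulationRecipe",
    "stick_pattern",
    "render",
    "make_benchmark",
    "BENCHMARK_NAMES",
]

MAX_STICKS = 10_000


@dataclass
class SpinSystemSpec:
    """One isotropic first-order spin system.

    The resonance field comes either from ``center_field_g`` directly or
    from ``center_g`` (a g value) with ``mw_frequency_ghz``.  ``couplings``
    is a list of ``(A_gauss, I, n_equivalent)`` hyperfine interactions.
    ``amplitude`` scales the absorption *area* (per-spin intensity), not the
    peak height, so equal-amplitude systems carry equal double integrals
    regardless of linewidth.
    """

    center_g: float | None = None
    center_field_g: float | None = None
    mw_frequency_ghz: float | None = None
    couplings: list[tuple[float, float, int]] = dc_field(default_factory=list)
    lineshape: str = "gaussian"
    linewidth_pp: float = 1.0
    amplitude: float = 1.0

    def center(self) -> float:
        if self.center_field_g is not None:
            return float(self.center_field_g)
        if self.center_g is None or self.mw_frequency_ghz is None:
            raise ValueError(
                "need either center_field_g or (center_g, mw_frequency_ghz)"
            )
        return G_PER_GHZ * self.mw_frequency_ghz / self.center_g

    def __post_init__(self) -> None:
        if self.linewidth_pp <= 0:
            raise ValueError("linewidth_pp must be positive")
        if self.lineshape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown lineshape {self.lineshape!r}")
        for a, spin, n in self.couplings:
            if a < 0:
                raise ValueError("couplings must have A >= 0")
            if n < 1 or abs(2 * spin - round(2 * spin)) > 1e-9 or spin <= 0:
                raise ValueError(f"bad coupling ({a}, {spin}, {n})")


@dataclass
class SimulationRecipe:
    """A reproducible multi-system simulation: same recipe + seed, same
    bits."""

    systems: list[tuple[SpinSystemSpec, float]]
    field_range: tuple[float, float]
    n_points: int = 1024
    noise_sigma: float = 0.0
    seed: int = 0
    mw_frequency_ghz: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_points < 64:
            raise ValueError("n_points must be >= 64")
        if self.field_range[1] <= self.field_range[0]:
            raise ValueError("field_range must be increasing")


def stick_pattern(s: SpinSystemSpec) -> list[tuple[float, float]]:
    """First-order stick spectrum: (position_G, relative_intensity) pairs.

    For each coupling the pattern is convolved with the single-nucleus
    (2I+1)-line comb n times; degenerate positions merge with summed
    intensities, so n equivalent nuclei give exactly 2nI+1 sticks with
    multinomial ratios.  Total intensity is normalized to 1.
    """
    positions = np.array([0.0])
    weights = np.array([1.0])
    for a, spin, n in s.couplings:
        m_values = np.arange(-spin, spin + 0.5, 1.0)  # 2I+1 projections
        for _ in range(n):
            new_pos = (positions[:, None] + a * m_values[None, :]).ravel()
            new_w = np.repeat(weights, len(m_values))
            # merge degenerate positions
            order = np.argsort(new_pos)
            new_pos, new_w = new_pos[order], new_w[order]
            tol = 1e-9 * max(1.0, a)
            merged_pos, merged_w = [], []
            for pos, w in zip(new_pos, new_w):
                if merged_pos and pos - merged_pos[-1] <= tol:
                    merged_w[-1] += w
                else:
                    merged_pos.append(pos)
                    merged_w.append(w)
            positions = np.array(merged_pos)
            weights = np.array(merged_w)
            if len(positions) > MAX_STICKS:
                raise ValueError(
                    f"stick pattern exceeds {MAX_STICKS} lines"
                )
    weights = weights / weights.sum()
    b0 = s.center()
    return [(float(b0 + p), float(w)) for p, w in zip(positions, weights)]


def _derivative_lineshape(x: np.ndarray, lineshape: str, pp_width: float):
    """First derivative of a unit-area absorption line, pp width in G."""
    if lineshape == "gaussian":
        sigma = pp_width / 2.0  # derivative extrema at +/- sigma
        norm = 1.0 / (sigma * math.sqrt(2.0 * math.pi))
        return -x / sigma**2 * norm * np.exp(-0.5 * (x / sigma) ** 2)
    # lorentzian: derivative extrema at +/- gamma/sqrt(3)
    gamma = math.sqrt(3.0) * pp_width / 2.0
    return -(2.0 / math.pi) * gamma * x / (x**2 + gamma**2) ** 2


def render(recipe: SimulationRecipe) -> Spectrum:
    """Render a recipe to a derivative-mode spectrum with attached truth.

    Sticks falling closer than 5 linewidths to the field range edge set a
    ``range_warning`` flag in the metadata instead of raising.
    """
    lo, hi = recipe.field_range
    field = np.linspace(lo, hi, recipe.n_points)
    clean = np.zeros_like(field)
    warn = False
    for system, weight in recipe.systems:
        for pos, inten in stick_pattern(system):
            margin = 5.0 * system.linewidth_pp
            if pos - margin < lo or pos + margin > hi:
                warn = True
            clean += (
                weight
                * system.amplitude
                * inten
                * _derivative_lineshape(field - pos, system.lineshape,
                                        system.linewidth_pp)
            )
    scale = float(np.max(np.abs(clean)))
    if scale == 0.0:  # pure-noise recipes: fall back to unit reference
        scale = 1.0
    rng = np.random.default_rng(recipe.seed)
    noise = rng.standard_normal(recipe.n_points) * recipe.noise_sigma * scale
    meta = {
        "truth": {
            "systems": [
                {
                    "center_field_g": sys.center(),
                    "couplings": [list(c) for c in sys.couplings],
                    "lineshape": sys.lineshape,
                    "linewidth_pp_g": sys.linewidth_pp,
                    "amplitude": sys.amplitude,
                    "weight": w,
                }
                for sys, w in recipe.systems
            ],
            "noise_sigma": recipe.noise_sigma,
            "seed": recipe.seed,
        }
    }
    if warn:
        meta["range_warning"] = "sticks within 5 linewidths of range edge"
    return Spectrum(
        field=field,
        intensity=clean + noise,
        mw_frequency_ghz=recipe.mw_frequency_ghz,
        label=recipe.label,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# benchmark presets
#
# The nitroxide presets emulate a 14N triplet with proton superhyperfine
# structure broadened past visual resolution (the oxygen-broadening regime);
# the published proton splittings 0.20 G and 0.44 G are used as simulator
# *inputs*.  The Cu presets emulate the g-perp quartet of N2/N3-coordinated
# Cu(II) complexes; the *_full variants add a 4-line g-parallel manifold so
# that two-component mixtures show spatially separated multiplets with 17 G
# vs 16 G nitrogen splittings.  Values not printed anywhere (proton count,
# nitroxide 14N coupling, g-parallel parameters, linewidths, sampling) were
# chosen once as realistic X-band conditions; see docs/methods.md.

BENCHMARK_NAMES = (
    "tempo_like",
    "tempol_like",
    "cuqu_like",
    "cuqua_like",
    "cuqu_full",
    "cuqua_full",
    "mixture_panel",
)

MIXTURE_RATIOS = ((2, 1), (4, 1), (10, 1), (20, 1))
#: inspection-chosen analysis windows (G) for the mixture panel: the lowest
#: g-parallel multiplet of the major and of the minor component
MIXTURE_WINDOWS = ((2603.0, 2679.0), (2706.0, 2794.0))
MIXTURE_SPACINGS = {"cuqu": 17.0, "cuqua": 16.0}


def _nitroxide(name, a_fine, linewidth, noise_sigma, seed, n_points,
               half_span):
    nu = 9.33
    b0 = G_PER_GHZ * nu / 2.0061
    system = SpinSystemSpec(
        center_field_g=b0,
        couplings=[(16.0, 1.0, 1), (a_fine, 0.5, 16)],
        lineshape="lorentzian",
        linewidth_pp=linewidth,
    )
    recipe = SimulationRecipe(
        systems=[(system, 1.0)],
        field_range=(b0 - half_span, b0 + half_span),
        n_points=n_points,
        noise_sigma=noise_sigma,
        seed=seed,
        mw_frequency_ghz=nu,
        label=name,
    )
    truth = {
        "A_fine": a_fine,
        "A_coarse": 16.0,
        "n_H": 4,
        "linewidth_pp": linewidth,
    }
    return render(recipe), truth


def _cu_gperp_system(g_perp, a_cu, a_n, n_n, linewidth, nu):
    return SpinSystemSpec(
        center_g=g_perp,
        mw_frequency_ghz=nu,
        couplings=[(a_cu, 1.5, 1), (a_n, 1.0, n_n)],
        lineshape="gaussian",
        linewidth_pp=linewidth,
    )


def _cu_quartet(name, g_perp, a_cu, a_n, n_n, linewidth, noise_sigma, seed):
    nu = 9.316
    system = _cu_gperp_system(g_perp, a_cu, a_n, n_n, linewidth, nu)
    b0 = system.center()
    recipe = SimulationRecipe(
        systems=[(system, 1.0)],
        field_range=(3000.0, 3560.0),
        n_points=256,
        noise_sigma=noise_sigma,
        seed=seed,
        mw_frequency_ghz=nu,
        label=name,
    )
    truth = {
        "A_fine": a_n,
        "n_nuclei": n_n,
        "m": 2 * n_n + 1,
        "A_cu": a_cu,
        "g_perp": g_perp,
        "h1": b0 - 1.5 * a_cu,
        "h4": b0 + 1.5 * a_cu,
    }
    return render(recipe), truth


def _cu_full(name, seed, noise_sigma=0.01):
    """Two-region Cu spectrum: g-perp quartet plus g-parallel manifold."""
    nu = 9.316
    if name == "cuqu_full":
        gperp = _cu_gperp_system(2.0427, 37.0, 26.5, 2, 14.0, nu)
        gpar = SpinSystemSpec(
            center_g=2.26,
            mw_frequency_ghz=nu,
            couplings=[(200.0, 1.5, 1), (17.0, 1.0, 2)],
            lineshape="gaussian",
            linewidth_pp=8.0,
            amplitude=0.5,
        )
        a_par = 17.0
    else:
        gperp = _cu_gperp_system(2.0411, 23.3, 21.3, 3, 11.0, nu)
        gpar = SpinSystemSpec(
            center_g=2.2409,
            mw_frequency_ghz=nu,
            couplings=[(150.0, 1.5, 1), (16.0, 1.0, 3)],
            lineshape="gaussian",
            linewidth_pp=6.0,
            amplitude=0.5,
        )
        a_par = 16.0
    recipe = SimulationRecipe(
        systems=[(gperp, 1.0), (gpar, 1.0)],
        field_range=(2400.0, 3500.0),
        n_points=768,
        noise_sigma=noise_sigma,
        seed=seed,
        mw_frequency_ghz=nu,
        label=name,
    )
    truth = {
        "A_par_fine": a_par,
        "gpar_centers": [
            gpar.center() + k * gpar.couplings[0][0] for k in (-1.5, -0.5, 0.5, 1.5)
        ],
    }
    return render(recipe), truth


def make_benchmark(name: str, seed: int = 0, **overrides):
    """Build a named benchmark: a list of (Spectrum, truth-dict) pairs.

    Overrides: ``linewidth`` (nitroxide presets), ``noise_sigma``.
    """
    if name not in BENCHMARK_NAMES:
        raise ValueError(f"unknown benchmark {name!r}; choose {BENCHMARK_NAMES}")
    noise = overrides.get("noise_sigma")
    if name == "tempo_like":
        lw = overrides.get("linewidth", 0.25)
        return [_nitroxide(name, 0.20, lw, 0.02 if noise is None else noise,
                           seed, 4096, 43.0)]
    if name == "tempol_like":
        lw = overrides.get("linewidth", 0.55)
        return [_nitroxide(name, 0.44, lw, 0.02 if noise is None else noise,
                           seed, 4096, 47.3)]
    if name == "cuqu_like":
        return [_cu_quartet(name, 2.0427, 37.0, 26.5, 2, 16.0,
                            0.01 if noise is None else noise, seed)]
    if name == "cuqua_like":
        return [_cu_quartet(name, 2.0411, 23.3, 21.3, 3, 13.0,
                            0.01 if noise is None else noise, seed)]
    if name in ("cuqu_full", "cuqua_full"):
        return [_cu_full(name, seed, 0.01 if noise is None else noise)]
    # mixture_panel
    from .mixtures import MixtureSpec, mix  # local import: avoid cycle

    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    (a, _), = make_benchmark("cuqu_full", int(seeds[0]), **overrides)
    (b, _), = make_benchmark("cuqua_full", int(seeds[1]), **overrides)
    out = []
    for wa, wb in MIXTURE_RATIOS:
        mixed = mix(MixtureSpec([(a, float(wa)), (b, float(wb))]))
        truth = {
            "ratio": f"{wa}:{wb}",
            "minor_fraction": wb / (wa + wb),
            "spacings": dict(MIXTURE_SPACINGS),
            "windows": [list(w) for w in MIXTURE_WINDOWS],
            "minor_label": "cuqua",
        }
        out.append((mixed, truth))
    return out
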