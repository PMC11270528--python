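"""Synthetic J-Res spectra: pure-compound signatures and mixture datasets.

The simulator produces high-resolution training/test material in the way a
spectral library would: each metabolite is a set of first-order multiplets
(chemical shift centre, scalar couplings, relative integral), rendered onto
the 2D grid as separable lineshapes and combined linearly with
normally-distributed concentrations.  Under first-order splitting a proton
coupled to k partners produces 2^k lines at offsets ±J_k/2 summed over the
couplings, with binomial-like intensity merging when offsets coincide —
a doublet for one coupling, a doublet of doublets (or, if the couplings are
equal, a 1:2:1 triplet) for two, and so on.  J-Res spectra are symmetric
about the J = 0 Hz line, and the rendered grids inherit that symmetry
exactly.

The packaged metabolite library is parametric and seeded, emulating the
statistical character (shift coverage, coupling ranges, integral spread) of
small-molecule signatures in urine or plasma rather than any particular
compound list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .core_io import Axis, Spectrum2D, default_f1_axis, default_f2_axis

__all__ = [
    "Multiplet",
    "scaled_linewidths",
    "Metabolite",
    "MixtureConfig",
    "multiplet_components",
    "render_metabolite",
    "sample_concentration",
    "simulate_mixture",
    "build_dataset",
    "default_library",
    "save_library",
    "load_library",
]


@dataclass(frozen=True)
class Multiplet:
    """One first-order multiplet of a compound's J-Res signature.

    delta : chemical shift centre (ppm)
    couplings : scalar coupling constants J (Hz); empty list = singlet
    proton_weight : relative integral (number of contributing protons)
    lw_f1 : full width at half maximum along F1 (Hz), Gaussian
    lw_f2 : full width at half maximum along F2 (ppm), Lorentzian
    """

    delta: float
    couplings: tuple[float, ...] = ()
    proton_weight: float = 1.0
    lw_f1: float = 0.4
    lw_f2: float = 0.002

    def __post_init__(self) -> None:
        object.__setattr__(self, "couplings", tuple(float(j) for j in self.couplings))
        if any(j < 0 or not np.isfinite(j) for j in self.couplings):
            raise ValueError("couplings must be finite and >= 0")
        if self.proton_weight <= 0:
            raise ValueError("proton_weight must be positive")
        if self.lw_f1 <= 0 or self.lw_f2 <= 0:
            raise ValueError("linewidths must be positive")


@dataclass(frozen=True)
class Metabolite:
    """A named compound: its multiplets and concentration distribution."""

    name: str
    multiplets: tuple[Multiplet, ...]
    conc_mean: float = 1.0
    conc_sd: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "multiplets", tuple(self.multiplets))
        if self.conc_mean <= 0:
            raise ValueError("conc_mean must be positive")
        if self.conc_sd < 0:
            raise ValueError("conc_sd must be non-negative")


@dataclass
class MixtureConfig:
    """Dataset recipe: which mixture sizes, how many spectra each, what grid.

    The training default draws 1000 spectra for each of five mixture sizes
    (6, 8, 15, 34, 40 metabolites); the test default is one spectrum for
    each of six plasma-style sizes (1, 3, 6, 9, 12, 15).
    """

    metabolite_counts: tuple[int, ...] = (6, 8, 15, 34, 40)
    spectra_per_type: int = 1000
    f1_axis: Axis = field(default_factory=default_f1_axis)
    f2_axis: Axis = field(default_factory=default_f2_axis)
    seed: int = 0

    def __post_init__(self) -> None:
        self.metabolite_counts = tuple(int(c) for c in self.metabolite_counts)
        if any(c < 1 for c in self.metabolite_counts):
            raise ValueError("metabolite counts must be >= 1")
        if self.spectra_per_type < 1:
            raise ValueError("spectra_per_type must be >= 1")


def multiplet_components(couplings) -> list[tuple[float, float]]:
    """First-order splitting pattern: (offset Hz, relative intensity) lines.

    Each coupling J splits every existing line into two at ±J/2 with half
    the intensity; coincident offsets are merged.  Intensities sum to 1 and
    the pattern is symmetric about offset 0.
    """
    pattern: dict[float, float] = {0.0: 1.0}
    for j in couplings:
        j = float(j)
        if j < 0 or not np.isfinite(j):
            raise ValueError("couplings must be finite and >= 0")
        nxt: dict[float, float] = {}
        for off, inten in pattern.items():
            for s in (-0.5, 0.5):
                # round to merge float-coincident offsets from equal couplings
                key = round(off + s * j, 9)
                nxt[key] = nxt.get(key, 0.0) + 0.5 * inten
        pattern = nxt
    return sorted((off, inten) for off, inten in pattern.items())


def _gaussian_profile(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    # unit-area Gaussian parameterized by FWHM
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    z = (x - center) / sigma
    return np.exp(-0.5 * z * z) / (sigma * np.sqrt(2.0 * np.pi))


def _lorentzian_profile(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    # unit-area Lorentzian parameterized by FWHM
    hwhm = fwhm / 2.0
    return (hwhm / np.pi) / ((x - center) ** 2 + hwhm * hwhm)


def render_metabolite(
    m: Metabolite,
    f1_axis: Axis | None = None,
    f2_axis: Axis | None = None,
) -> Spectrum2D:
    """Render one metabolite's J-Res signature onto a grid.

    Each multiplet component becomes a separable 2D peak: a unit-area
    Gaussian along F1 centred at the component offset and a unit-area
    Lorentzian along F2 centred at the chemical shift, scaled by
    proton_weight x component intensity.  The grid double-integral of the
    signature therefore equals the total proton weight.  Because the F1
    pixel centres are symmetric about J = 0 and component offsets negate
    pairwise, the output is symmetric under an F1 flip to float32 rounding.
    """
    f1_axis = f1_axis or default_f1_axis()
    f2_axis = f2_axis or default_f2_axis()
    f1 = f1_axis.centers()
    f2 = f2_axis.centers()
    f1_lo, f1_hi = sorted((f1_axis.start, f1_axis.end))
    f2_lo, f2_hi = sorted((f2_axis.start, f2_axis.end))
    grid = np.zeros((f1_axis.n_points, f2_axis.n_points), dtype=np.float64)
    for k, mp in enumerate(m.multiplets):
        if not (f2_lo <= mp.delta <= f2_hi):
            raise ValueError(
                f"metabolite {m.name!r} multiplet {k}: centre {mp.delta} ppm "
                f"outside F2 range [{f2_lo}, {f2_hi}]"
            )
        comps = multiplet_components(mp.couplings)
        max_off = max(abs(c[0]) for c in comps)
        if not (f1_lo <= -max_off and max_off <= f1_hi):
            raise ValueError(
                f"metabolite {m.name!r} multiplet {k}: offset ±{max_off} Hz "
                f"outside F1 range [{f1_lo}, {f1_hi}]"
            )
        col = _lorentzian_profile(f2, mp.delta, mp.lw_f2)
        for off, inten in comps:
            row = _gaussian_profile(f1, off, mp.lw_f1)
            grid += (mp.proton_weight * inten) * np.outer(row, col)
    return Spectrum2D(grid, f1_axis, f2_axis, label=m.name)


def sample_concentration(m: Metabolite, rng: np.random.Generator) -> float:
    """Draw a concentration from Normal(mean, sd), truncated at 0 by resampling."""
    if m.conc_sd == 0.0:
        return m.conc_mean
    while True:
        c = rng.normal(m.conc_mean, m.conc_sd)
        if c >= 0.0:
            return float(c)


def simulate_mixture(
    library: list[Metabolite],
    n_metab: int,
    f1_axis: Axis | None = None,
    f2_axis: Axis | None = None,
    rng: np.random.Generator | None = None,
    concentrations: dict[str, float] | None = None,
    _render_cache: dict | None = None,
) -> Spectrum2D:
    """Linear combination of ``n_metab`` randomly chosen library signatures.

    Concentrations are drawn per metabolite (truncated normal) unless given
    explicitly; the chosen names and concentrations are recorded in the
    result's ``meta``.  ``_render_cache`` lets dataset builders reuse
    rendered pure-compound grids across mixtures.
    """
    if n_metab > len(library):
        raise ValueError(f"n_metab={n_metab} exceeds library size {len(library)}")
    f1_axis = f1_axis or default_f1_axis()
    f2_axis = f2_axis or default_f2_axis()
    rng = rng or np.random.default_rng()
    idx = rng.choice(len(library), size=n_metab, replace=False)
    chosen = [library[i] for i in sorted(idx)]
    grid = np.zeros((f1_axis.n_points, f2_axis.n_points), dtype=np.float64)
    conc_used: dict[str, float] = {}
    for m in chosen:
        if concentrations is not None:
            c = float(concentrations[m.name])
        else:
            c = sample_concentration(m, rng)
        conc_used[m.name] = c
        if _render_cache is not None:
            key = (m.name, f1_axis.n_points, f2_axis.n_points)
            if key not in _render_cache:
                _render_cache[key] = render_metabolite(m, f1_axis, f2_axis).grid.astype(np.float64)
            pure = _render_cache[key]
        else:
            pure = render_metabolite(m, f1_axis, f2_axis).grid.astype(np.float64)
        grid += c * pure
    spec = Spectrum2D(grid, f1_axis, f2_axis)
    spec.meta = {
        "metabolites": ",".join(conc_used),
        "concentrations": ",".join(f"{v:.6g}" for v in conc_used.values()),
        "n_metabolites": n_metab,
    }
    return spec


def build_dataset(cfg: MixtureConfig, library: list[Metabolite]) -> list[Spectrum2D]:
    """Build the full HR dataset: counts x spectra_per_type mixtures.

    Reproducible from ``cfg.seed``; each spectrum carries its metabolite
    subset and sampled concentrations in ``meta``.
    """
    if max(cfg.metabolite_counts) > len(library):
        raise ValueError("library smaller than the largest mixture size")
    rng = np.random.default_rng(cfg.seed)
    cache: dict = {}
    out: list[Spectrum2D] = []
    for count in cfg.metabolite_counts:
        for rep in range(cfg.spectra_per_type):
            spec = simulate_mixture(
                library, count, cfg.f1_axis, cfg.f2_axis, rng, _render_cache=cache
            )
            spec.label = f"mix{count:02d}_{rep:04d}"
            out.append(spec)
    return out


# ---------------------------------------------------------------------------
# Packaged parametric library
# ---------------------------------------------------------------------------

def default_library(
    n_metabolites: int = 40,
    seed: int = 20240,
    f2_range: tuple[float, float] = (0.5, 9.5),
    coupling_range: tuple[float, float] = (2.0, 18.0),
    lw_f1: float = 0.4,
    lw_f2: float = 0.002,
) -> list[Metabolite]:
    """Seeded parametric library of synthetic metabolite signatures.

    Each compound gets 1-4 multiplets with shifts in ``f2_range`` ppm, up to
    three couplings each in ``coupling_range`` Hz, proton weights 1-9, and a
    truncated-normal concentration distribution (mean 0.2-5 a.u., sd set to
    10-50% of the mean) reflecting the spread of abundances in biofluids.

    The default linewidths span 1-2 pixels on the reference 256 x 16384
    grid.  When rendering onto a coarser grid, pass linewidths scaled by
    the pixel-width ratio (see :func:`scaled_linewidths`) so that peaks
    remain resolved over the same number of pixels; otherwise sub-pixel
    peaks degenerate to single-pixel spikes.
    """
    rng = np.random.default_rng(seed)
    library: list[Metabolite] = []
    for i in range(n_metabolites):
        multiplets = []
        for _ in range(int(rng.integers(1, 5))):
            n_j = int(rng.integers(0, 4))
            couplings = tuple(np.round(rng.uniform(*coupling_range, size=n_j), 2))
            multiplets.append(
                Multiplet(
                    delta=float(np.round(rng.uniform(*f2_range), 4)),
                    couplings=couplings,
                    proton_weight=float(rng.integers(1, 10)),
                    lw_f1=lw_f1,
                    lw_f2=lw_f2,
                )
            )
        mean = float(np.round(rng.uniform(0.2, 5.0), 3))
        sd = float(np.round(mean * rng.uniform(0.1, 0.5), 3))
        library.append(
            Metabolite(name=f"synmet{i:02d}", multiplets=tuple(multiplets),
                       conc_mean=mean, conc_sd=sd)
        )
    return library


def scaled_linewidths(f1_points: int, f2_points: int,
                      lw_f1: float = 0.4, lw_f2: float = 0.002,
                      ref: tuple[int, int] = (256, 16384)) -> tuple[float, float]:
    """Linewidths for a reduced grid preserving the FWHM in pixels.

    The reference linewidths correspond to the full 256 x 16384 grid; a
    grid with fewer points over the same ranges has proportionally wider
    pixels, so linewidths are widened by the same ratio to keep the peak
    shapes sampled by the same number of pixels.
    """
    return (lw_f1 * ref[0] / f1_points, lw_f2 * ref[1] / f2_points)


def save_library(library: list[Metabolite], path: str) -> None:
    """Write a metabolite library to YAML."""
    doc = [
        {
            "name": m.name,
            "conc_mean": m.conc_mean,
            "conc_sd": m.conc_sd,
            "multiplets": [
                {
                    "delta": mp.delta,
                    "couplings": list(mp.couplings),
                    "proton_weight": mp.proton_weight,
                    "lw_f1": mp.lw_f1,
                    "lw_f2": mp.lw_f2,
                }
                for mp in m.multiplets
            ],
        }
        for m in library
    ]
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)


def load_library(path: str) -> list[Metabolite]:
    """Read a metabolite library from YAML."""
    with open(path) as f:
        doc = yaml.safe_load(f)
    return [
        Metabolite(
            name=entry["name"],
            multiplets=tuple(
                Multiplet(
                    delta=mp["delta"],
                    couplings=tuple(mp.get("couplings", ())),
                    proton_weight=mp.get("proton_weight", 1.0),
                    lw_f1=mp.get("lw_f1", 0.4),
                    lw_f2=mp.get("lw_f2", 0.002),
                )
                for mp in entry["multiplets"]
            ),
            conc_mean=entry.get("conc_mean", 1.0),
            conc_sd=entry.get("conc_sd", 0.0),
        )
        for entry in doc
    ]
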