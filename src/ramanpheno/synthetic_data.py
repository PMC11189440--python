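"""Synthetic single-cell Raman cohorts with known ground truth.

Generates spectra as sums of Lorentzian (or Gaussian) band profiles on top of
a smooth fluorescence-like baseline, with per-cell amplitude variability,
donor-level batch effects (multiplicative intensity, rigid axis shift),
additive Gaussian noise, cosmic-ray spikes, class imbalance, and sort-purity
label corruption.  Everything planted is returned in a :class:`GroundTruth`
record so downstream stages can be tested against known answers.

Class effects are small fractional amplitude shifts on a subset of bands,
deliberately far below the per-cell variability (which is dominated by a
shared global-intensity factor — the component a linear model can project
out).  Per-channel noise defaults are conventions, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra_io import SpectrumSet, make_metadata


# ---------------------------------------------------------------------------
# axis

def make_axis(start: float, stop: float, n_channels: int) -> np.ndarray:
    """Uniform wavenumber grid from start to stop (inclusive) in cm^-1."""
    if start >= stop:
        raise ValueError(f"start ({start}) must be < stop ({stop})")
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    return np.linspace(float(start), float(stop), int(n_channels))


def default_axis() -> np.ndarray:
    """Default acquisition grid: 600-3050 cm^-1, 1016 channels.

    Chosen so that excising the 1800-2700 cm^-1 silent region leaves exactly
    643 channels.
    """
    return make_axis(600.0, 3050.0, 1016)


# ---------------------------------------------------------------------------
# templates

@dataclass
class BandSpec:
    """One vibrational band of the generative model.

    ``width`` is the half-width at half-maximum.  ``class_effect`` is the
    signed fractional amplitude difference of Treg relative to Tconv;
    ``cell_cv`` the coefficient of variation of the independent per-cell
    amplitude jitter of this band.
    """

    center: float
    width: float
    base_amplitude: float
    class_effect: float = 0.0
    cell_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be > 0")
        if self.base_amplitude < 0:
            raise ValueError("band amplitude must be >= 0")
        if self.cell_cv < 0:
            raise ValueError("cell_cv must be >= 0")


@dataclass
class PhenotypeTemplate:
    """Generative spectrum model for a Tconv/Treg pair of phenotypes."""

    shared_bands: list[BandSpec]
    discriminative_bands: list[BandSpec]
    baseline_coefficients: list[float] = field(
        default_factory=lambda: [0.5, -0.35, 0.15]
    )
    profile_kind: str = "lorentzian"
    #: CV of the per-cell global intensity factor shared by all bands.
    global_intensity_cv: float = 0.15
    #: CV of the per-cell baseline scale.
    baseline_cv: float = 0.3

    def __post_init__(self) -> None:
        if not self.shared_bands:
            raise ValueError("template needs at least one shared band")
        if self.profile_kind not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown profile kind {self.profile_kind!r}")

    @property
    def bands(self) -> list[BandSpec]:
        return list(self.shared_bands) + list(self.discriminative_bands)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhenotypeTemplate":
        d = dict(d)
        d["shared_bands"] = [BandSpec(**b) for b in d["shared_bands"]]
        d["discriminative_bands"] = [
            BandSpec(**b) for b in d["discriminative_bands"]
        ]
        return cls(**d)


_SHARED_BANDS = [
    # center, HWHM, amplitude — a generic cellular fingerprint + CH region.
    # Widths keep every line oversampled (FWHM >= ~8 channels on the default
    # grid) so band tops are never despiked as cosmic rays.
    (622, 10, 0.20), (645, 10, 0.15), (758, 10, 0.35), (782, 10, 0.45),
    (830, 10, 0.25), (880, 11, 0.25), (940, 11, 0.30), (1004, 10, 1.00),
    (1095, 12, 0.40), (1127, 11, 0.30), (1208, 11, 0.25), (1255, 14, 0.60),
    (1305, 12, 0.45), (1340, 12, 0.45), (1485, 12, 0.25), (1578, 10, 0.35),
    (1660, 15, 0.85), (2855, 18, 0.35), (2935, 22, 1.20), (3010, 14, 0.25),
]

# Discriminative centers/signs follow the murine band list (negative bands
# mark Tconv, positive mark Treg); effect sizes are a tuning convention.
_DISCRIMINATIVE_BANDS = [
    (734, 10, 0.40, -0.062), (855, 10, 0.35, -0.05), (1233, 11, 0.45, -0.062),
    (1316, 11, 0.40, -0.05), (1559, 10, 0.30, -0.062),
    (1008, 10, 0.45, +0.05), (1034, 10, 0.40, +0.05), (1181, 10, 0.30, +0.062),
    (1410, 11, 0.30, +0.05), (1449, 12, 0.70, +0.038), (1603, 10, 0.35, +0.062),
    (1735, 11, 0.20, +0.062),
]

DEFAULT_CELL_CV = 0.07


def default_template(
    effect_scale: float = 1.0, cell_cv: float = DEFAULT_CELL_CV
) -> PhenotypeTemplate:
    """Default two-phenotype template.

    ``effect_scale`` multiplies every planted class effect (0 gives a null
    cohort with no class signal); ``cell_cv`` sets the independent per-band
    amplitude jitter.
    """
    shared = [
        BandSpec(c, w, a, 0.0, cell_cv) for c, w, a in _SHARED_BANDS
    ]
    disc = [
        BandSpec(c, w, a, e * effect_scale, cell_cv)
        for c, w, a, e in _DISCRIMINATIVE_BANDS
    ]
    return PhenotypeTemplate(shared_bands=shared, discriminative_bands=disc)


# ---------------------------------------------------------------------------
# cohort configuration / ground truth

@dataclass
class CohortConfig:
    """Design of a simulated multi-donor cohort."""

    n_donors: int = 3
    cells_per_donor: int = 300
    tconv_to_treg_ratio: float = 2.0
    purity_tconv: float = 1.0
    purity_treg: float = 1.0
    frIII_cells_per_donor: int = 0
    frIII_fraction_treg: float | Sequence[float] = 0.5
    batch_intensity_sd: float = 0.0
    batch_shift_sd: float = 0.0
    noise_sd: float = 0.02
    cosmic_ray_rate: float = 0.0
    cosmic_ray_amplitude: float = 50.0
    cosmic_ray_width: int = 1
    seed: int = 0
    #: optional explicit acquisition grid; default_axis() if None
    axis: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")
        if self.cells_per_donor < 1 and self.frIII_cells_per_donor < 1:
            raise ValueError("cohort must contain at least one cell")
        if self.tconv_to_treg_ratio < 1:
            raise ValueError("tconv_to_treg_ratio must be >= 1")
        for name in ("purity_tconv", "purity_treg"):
            p = getattr(self, name)
            if not (0.5 < p <= 1.0):
                raise ValueError(f"{name} must be in (0.5, 1], got {p}")
        if self.cosmic_ray_width < 1:
            raise ValueError("cosmic_ray_width must be >= 1")

    def frIII_fraction_for(self, donor_index: int) -> float:
        if np.isscalar(self.frIII_fraction_treg):
            return float(self.frIII_fraction_treg)
        return float(self.frIII_fraction_treg[donor_index])

    def to_dict(self) -> dict:
        d = asdict(self)
        if not np.isscalar(d["frIII_fraction_treg"]):
            d["frIII_fraction_treg"] = [
                float(v) for v in d["frIII_fraction_treg"]
            ]
        if d["axis"] is not None:
            d["axis"] = [float(v) for v in d["axis"]]
        return d


@dataclass
class GroundTruth:
    """Everything planted by :func:`simulate_cohort`."""

    cells: pd.DataFrame       # cell_id, donor_id, true_label, sorted_label, corrupted
    band_effects: pd.DataFrame  # center, class_effect
    spikes: pd.DataFrame      # cell_id, channel
    donor_effects: pd.DataFrame  # donor_id, intensity_scale, axis_shift
    config: dict


# ---------------------------------------------------------------------------
# rendering

def _profiles(
    template: PhenotypeTemplate, axis: np.ndarray, validate: bool = True
) -> np.ndarray:
    """Band profile matrix, shape (n_bands, n_channels), unit peak height."""
    centers = np.array([b.center for b in template.bands])
    widths = np.array([b.width for b in template.bands])
    lo, hi = axis[0], axis[-1]
    if validate:
        off = (centers < lo) | (centers > hi)
        if off.any():
            raise ValueError(
                f"band center {centers[off][0]:.1f} cm^-1 is off-axis "
                f"[{lo:.1f}, {hi:.1f}]"
            )
    u = (axis[None, :] - centers[:, None]) / widths[:, None]
    if template.profile_kind == "lorentzian":
        return 1.0 / (1.0 + u * u)
    return np.exp(-np.log(2.0) * u * u)


def _baseline(template: PhenotypeTemplate, axis: np.ndarray) -> np.ndarray:
    t = (axis - axis[0]) / (axis[-1] - axis[0])
    out = np.zeros_like(axis)
    for k, c in enumerate(template.baseline_coefficients):
        out += c * t**k
    return out


def draw_cell(template: PhenotypeTemplate, rng: np.random.Generator) -> dict:
    """Draw per-cell nuisance parameters (amplitudes + baseline scale)."""
    g = np.exp(rng.normal(0.0, template.global_intensity_cv))
    amps = np.array(
        [
            b.base_amplitude
            * g
            * np.exp(rng.normal(0.0, b.cell_cv) if b.cell_cv > 0 else 0.0)
            for b in template.bands
        ]
    )
    bscale = np.exp(rng.normal(0.0, template.baseline_cv))
    return {"band_amplitudes": amps, "baseline_scale": bscale}


def _class_factors(template: PhenotypeTemplate, label: str) -> np.ndarray:
    f = np.ones(len(template.bands))
    if label == "Treg":
        n_shared = len(template.shared_bands)
        for j, b in enumerate(template.discriminative_bands):
            f[n_shared + j] = 1.0 + b.class_effect
    return f


def render_spectrum(
    template: PhenotypeTemplate,
    label: str,
    axis: np.ndarray,
    cell_draws: dict,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
    axis_shift: float = 0.0,
) -> np.ndarray:
    """Render one spectrum from explicit per-cell draws.

    Discriminative band amplitudes are scaled by ``1 + class_effect`` iff the
    label is Treg.  ``axis_shift`` rigidly displaces every band center
    (batch miscalibration).  Additive Gaussian noise requires an rng.
    """
    if label not in ("Tconv", "Treg"):
        raise ValueError(f"label must be Tconv or Treg, got {label!r}")
    shifted = template if axis_shift == 0.0 else _shifted_template(
        template, axis_shift
    )
    prof = _profiles(shifted, axis)
    amps = np.asarray(cell_draws["band_amplitudes"]) * _class_factors(
        template, label
    )
    y = amps @ prof + cell_draws["baseline_scale"] * _baseline(template, axis)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        y = y + rng.normal(0.0, noise_sd, size=axis.size)
    return y


def restrict_template(
    template: PhenotypeTemplate, axis: np.ndarray
) -> PhenotypeTemplate:
    """Drop bands whose centers fall outside the axis span."""
    lo, hi = axis[0], axis[-1]

    def keep(bands: list[BandSpec]) -> list[BandSpec]:
        return [b for b in bands if lo <= b.center <= hi]

    return PhenotypeTemplate(
        shared_bands=keep(template.shared_bands),
        discriminative_bands=keep(template.discriminative_bands),
        baseline_coefficients=list(template.baseline_coefficients),
        profile_kind=template.profile_kind,
        global_intensity_cv=template.global_intensity_cv,
        baseline_cv=template.baseline_cv,
    )


def _shifted_template(
    template: PhenotypeTemplate, shift: float
) -> PhenotypeTemplate:
    def mv(b: BandSpec) -> BandSpec:
        return BandSpec(
            b.center + shift, b.width, b.base_amplitude, b.class_effect,
            b.cell_cv,
        )

    return PhenotypeTemplate(
        shared_bands=[mv(b) for b in template.shared_bands],
        discriminative_bands=[mv(b) for b in template.discriminative_bands],
        baseline_coefficients=list(template.baseline_coefficients),
        profile_kind=template.profile_kind,
        global_intensity_cv=template.global_intensity_cv,
        baseline_cv=template.baseline_cv,
    )


# ---------------------------------------------------------------------------
# label corruption

def corrupt_labels(
    true_labels: Sequence[str],
    purity_tconv: float,
    purity_treg: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Corrupt true labels so each *sorted* class hits its target purity.

    Returns (sorted_labels, corrupted_flags).  Independent per-cell flip
    rates are solved so that, in expectation, a fraction ``1 - purity_c`` of
    cells sorted into class c carry the other true label — the composition
    the purity validation of a sorter measures.
    """
    for name, p in (("purity_tconv", purity_tconv), ("purity_treg", purity_treg)):
        if not (0.5 < p <= 1.0):
            raise ValueError(f"{name} must be in (0.5, 1], got {p}")
    true = np.asarray(true_labels, dtype=object)
    is_treg = true == "Treg"
    n_r, n_t = int(is_treg.sum()), int((~is_treg).sum())
    sorted_labels = true.copy()
    flags = np.zeros(true.size, dtype=bool)
    draws = rng.random(true.size)  # consumed even at purity 1 (paired seeds)
    if purity_tconv == 1.0 and purity_treg == 1.0:
        return sorted_labels, flags
    if n_r == 0 or n_t == 0:
        raise ValueError("label corruption needs both true classes present")
    # u = true-Tconv cells landing in sorted-Treg, v = the converse
    p_r, p_c = purity_treg, purity_tconv
    a_mat = np.array([[p_r, 1.0 - p_r], [1.0 - p_c, p_c]])
    b_vec = np.array([(1.0 - p_r) * n_r, (1.0 - p_c) * n_t])
    u, v = np.linalg.solve(a_mat, b_vec)
    rate_tconv = min(max(u / n_t, 0.0), 1.0)  # P(flip | true Tconv)
    rate_treg = min(max(v / n_r, 0.0), 1.0)
    flip = np.where(is_treg, draws < rate_treg, draws < rate_tconv)
    sorted_labels[flip & is_treg] = "Tconv"
    sorted_labels[flip & ~is_treg] = "Treg"
    return sorted_labels, flip


# ---------------------------------------------------------------------------
# cohort simulation

def class_counts(cells_per_donor: int, ratio: float) -> tuple[int, int]:
    """Deterministic (n_tconv, n_treg) split at the configured ratio."""
    n_treg = int(round(cells_per_donor / (1.0 + ratio)))
    n_treg = max(n_treg, 1)
    return cells_per_donor - n_treg, n_treg


def simulate_cohort(
    template: PhenotypeTemplate, config: CohortConfig
) -> tuple[SpectrumSet, GroundTruth]:
    """Simulate a multi-donor cohort; fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    axis = default_axis() if config.axis is None else np.asarray(config.axis)
    # bands outside the configured grid simply do not appear in the data
    template = restrict_template(template, axis)

    all_rows: list[np.ndarray] = []
    meta_frames: list[pd.DataFrame] = []
    spike_records: list[tuple[str, int]] = []
    donor_records: list[dict] = []
    truth_frames: list[pd.DataFrame] = []

    base_profiles = _profiles(template, axis)  # unshifted, reused if shift 0
    baseline_vec = _baseline(template, axis)
    n_bands = len(template.bands)
    n_shared = len(template.shared_bands)
    disc_effects = np.array(
        [b.class_effect for b in template.discriminative_bands]
    )
    cvs = np.array([b.cell_cv for b in template.bands])
    base_amps = np.array([b.base_amplitude for b in template.bands])

    for di in range(config.n_donors):
        donor = f"d{di + 1}"
        # draws are always consumed so that sweeping an effect magnitude at a
        # fixed seed yields paired cohorts (common random numbers)
        shift = float(config.batch_shift_sd * rng.normal())
        scale = float(np.exp(config.batch_intensity_sd * rng.normal()))
        donor_records.append(
            {"donor_id": donor, "intensity_scale": scale, "axis_shift": shift}
        )
        if shift != 0.0:
            prof = _profiles(
                _shifted_template(template, shift), axis, validate=False
            )
        else:
            prof = base_profiles

        n_tc, n_tr = (
            class_counts(config.cells_per_donor, config.tconv_to_treg_ratio)
            if config.cells_per_donor > 0
            else (0, 0)
        )
        true = np.array(["Tconv"] * n_tc + ["Treg"] * n_tr, dtype=object)
        if true.size:
            sorted_lab, flags = corrupt_labels(
                true, config.purity_tconv, config.purity_treg, rng
            )
        else:
            sorted_lab = true.copy()
            flags = np.zeros(0, dtype=bool)

        # FrIII pool: planted Treg fraction, exact deterministic counts
        n_f = config.frIII_cells_per_donor
        if n_f > 0:
            frac = config.frIII_fraction_for(di)
            n_f_treg = int(round(n_f * frac))
            f_true = np.array(
                ["Tconv"] * (n_f - n_f_treg) + ["Treg"] * n_f_treg,
                dtype=object,
            )
            rng.shuffle(f_true)
            true = np.concatenate([true, f_true])
            sorted_lab = np.concatenate(
                [sorted_lab, np.array(["FrIII"] * n_f, dtype=object)]
            )
            flags = np.concatenate([flags, np.zeros(n_f, dtype=bool)])

        n_cells = true.size
        ids = [f"{donor}_c{j:05d}" for j in range(n_cells)]

        # vectorized per-cell draws
        g = np.exp(
            rng.normal(0.0, template.global_intensity_cv, size=n_cells)
        )
        jitter = np.exp(rng.normal(0.0, 1.0, size=(n_cells, n_bands)) * cvs)
        amps = base_amps[None, :] * g[:, None] * jitter
        treg_rows = true == "Treg"
        factors = np.ones((n_cells, n_bands))
        factors[np.ix_(treg_rows, np.arange(n_shared, n_bands))] = (
            1.0 + disc_effects
        )
        bscale = np.exp(rng.normal(0.0, template.baseline_cv, size=n_cells))
        y = (amps * factors) @ prof + bscale[:, None] * baseline_vec[None, :]
        y *= scale
        y += config.noise_sd * rng.normal(size=y.shape)

        if config.cosmic_ray_rate > 0:
            n_spikes = rng.poisson(config.cosmic_ray_rate, size=n_cells)
            amp = config.cosmic_ray_amplitude * config.noise_sd
            for i in np.flatnonzero(n_spikes):
                chans = rng.integers(0, axis.size, size=n_spikes[i])
                for ch in chans:
                    hi = min(int(ch) + config.cosmic_ray_width, axis.size)
                    y[i, ch:hi] += amp
                    for c in range(int(ch), hi):
                        spike_records.append((ids[i], c))

        all_rows.append(y)
        meta_frames.append(
            make_metadata(
                ids,
                donor_id=donor,
                batch_id=f"b{di + 1}",
                sorted_label=list(sorted_lab),
                true_label=list(true),
                subpop="mixed",
                qc_flag="pass",
            )
        )
        truth_frames.append(
            pd.DataFrame(
                {
                    "cell_id": ids,
                    "donor_id": donor,
                    "true_label": true,
                    "sorted_label": sorted_lab,
                    "corrupted": flags,
                }
            )
        )

    intensities = np.vstack(all_rows) if all_rows else np.empty((0, axis.size))
    meta = pd.concat(meta_frames, ignore_index=True)
    if len(meta) == 0:
        raise ValueError("configuration produced zero cells")
    sset = SpectrumSet(axis, intensities, meta)
    truth = GroundTruth(
        cells=pd.concat(truth_frames, ignore_index=True),
        band_effects=pd.DataFrame(
            {
                "center": [b.center for b in template.discriminative_bands],
                "class_effect": [
                    b.class_effect for b in template.discriminative_bands
                ],
            }
        ),
        spikes=pd.DataFrame(
            spike_records, columns=["cell_id", "channel"]
        ),
        donor_effects=pd.DataFrame(donor_records),
        config=config.to_dict(),
    )
    return sset, truth
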