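"""Synthetic 384-well high-content trafficking screen with planted hits.

The generator realizes the statistical structure of the imaging assay: each
well holds a population of cells whose surface- and total-channel intensities
are log-normal around the well mean (multiplicative cell-level CV), each plate
carries one multiplicative plate effect per channel, and control columns hold
DMSO-treated negative controls and a trafficking-deficient positive-control
line with depressed surface and total levels.  Planted hits perturb a
compound well's channel means either by an explicit multiplicative factor or
in MAD units of the expected null spread of well means; toxic compounds reduce
the well's expected cell count (cell count is the screen's toxicity
observable, intensities are untouched).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from traffickit._rng import substream
from traffickit.errors import ConfigurationError

ROWS = "ABCDEFGHIJKLMNOP"

ROLE_COMPOUND = "compound"
ROLE_NEG = "dmso_neg"
ROLE_POS = "e115g_pos"

_METRICS = ("surface", "total", "ratio")


def well_labels_384() -> list[str]:
    """A1..P24 in row-major order."""
    return [f"{r}{c}" for r in ROWS for c in range(1, 25)]


def default_control_layout() -> dict[str, str]:
    """Column 1 = DMSO negative controls, column 2 = E115G positive controls."""
    layout = {}
    for r in ROWS:
        layout[f"{r}1"] = ROLE_NEG
        layout[f"{r}2"] = ROLE_POS
    return layout


@dataclass(frozen=True)
class PlantedEffect:
    """A planted compound effect on one screen metric.

    Exactly one of ``factor`` (multiplicative, applied to the underlying
    channel mean) or ``mad_units`` (effect size in expected null-MAD units of
    the well-mean distribution, converted to a factor at generation time) must
    be given.  ``metric`` is ``surface``, ``total``, or ``ratio``; a ratio
    effect is planted by scaling the surface channel.
    """

    compound_id: str
    metric: str
    factor: float | None = None
    mad_units: float | None = None

    def __post_init__(self):
        if (self.factor is None) == (self.mad_units is None):
            raise ConfigurationError("specify exactly one of factor / mad_units")
        if self.metric not in _METRICS:
            raise ConfigurationError(f"unknown metric {self.metric!r}")
        if self.factor is not None and self.factor <= 0:
            raise ConfigurationError("factor must be > 0")


@dataclass
class ScreenSimConfig:
    """Study conditions for the synthetic screen.

    Intensity units are arbitrary fluorescence intensity units (FIU).  The
    positive-control factors put the E115G line well below the negative
    controls on both channels, as the screen's validation requires.
    ``n_cells_dispersion`` is the gamma shape of a gamma-Poisson mixture
    (``None`` = pure Poisson counts).
    """

    n_plates: int = 3
    wells_per_plate: int = 384
    n_cells_mean: float = 120.0
    n_cells_dispersion: float | None = None
    control_layout: dict[str, str] = field(default_factory=default_control_layout)
    baseline_surface: float = 1000.0
    baseline_total: float = 3000.0
    pos_surface_factor: float = 0.25
    pos_total_factor: float = 0.40
    cell_level_cv: float = 0.35
    well_level_cv: float = 0.0
    plate_effect_sd: float = 0.08
    planted_hits: tuple[PlantedEffect, ...] = ()
    toxic_compounds: dict[str, float] = field(default_factory=dict)
    compound_concentration_uM: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.wells_per_plate != 384:
            raise ConfigurationError("only 384-well plates (A1..P24) are supported")
        if min(self.baseline_surface, self.baseline_total) <= 0:
            raise ConfigurationError("baseline intensities must be > 0")
        if self.pos_surface_factor >= 1 or self.pos_total_factor >= 1:
            raise ConfigurationError("positive-control levels must sit below the negative controls")
        if min(self.cell_level_cv, self.well_level_cv, self.plate_effect_sd) < 0:
            raise ConfigurationError("noise parameters must be >= 0")
        if self.n_cells_mean <= 0:
            raise ConfigurationError("n_cells_mean must be > 0")
        valid = set(well_labels_384())
        for well, role in self.control_layout.items():
            if well not in valid:
                raise ConfigurationError(f"control layout references unknown well {well!r}")
            if role not in (ROLE_NEG, ROLE_POS, ROLE_COMPOUND):
                raise ConfigurationError(f"unknown role {role!r} for well {well}")

    # -- derived quantities -------------------------------------------------

    def compound_id_for(self, plate: int, well: str) -> str:
        return f"C{plate:03d}-{well}"

    def null_relative_sd(self, metric: str = "surface") -> float:
        """Expected relative SD of a null compound well's mean for ``metric``.

        Combines cell-sampling noise (cell CV over ~n cells) with any
        well-level noise; the per-cell trafficking ratio divides two
        independent channels, doubling the variance.  Used to convert
        MAD-unit effect sizes into factors (the consistency-scaled MAD of
        null well means ~= this SD times the mean).
        """
        chan = 2.0 if metric == "ratio" else 1.0
        return float(
            np.sqrt(chan * (self.cell_level_cv**2 / self.n_cells_mean + self.well_level_cv**2))
        )

    def effect_factor(self, eff: PlantedEffect) -> float:
        if eff.factor is not None:
            return eff.factor
        f = 1.0 + eff.mad_units * self.null_relative_sd(eff.metric)
        if f <= 0:
            raise ConfigurationError(
                f"{eff.compound_id}: MAD-unit effect implies a non-positive factor"
            )
        return f


def _lognormal_around_mean(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    """Log-normal draws with arithmetic mean ``mean`` and relative SD ``cv``."""
    if cv == 0:
        return np.full(size, mean, dtype=float)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def simulate_screen(
    config: ScreenSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic screen.

    Returns ``(cells, plate_map, truth)``:

    * ``cells`` -- per-cell table ``plate_id, well, compound_id, cell_id,
      surface_fiu, total_fiu`` (one row per simulated cell);
    * ``plate_map`` -- ``plate_id, well, role, compound_id, concentration_uM``;
    * ``truth`` -- planted effects and toxic compounds with the multiplicative
      factors actually applied.

    Deterministic given ``config.seed``; each plate draws from its own
    substream so single plates can be regenerated in isolation.
    """
    config.validate()
    labels = well_labels_384()

    known_compounds = {
        config.compound_id_for(p, w)
        for p in range(1, config.n_plates + 1)
        for w in labels
        if config.control_layout.get(w, ROLE_COMPOUND) == ROLE_COMPOUND
    }
    effects: dict[str, list[PlantedEffect]] = {}
    for eff in config.planted_hits:
        if eff.compound_id not in known_compounds:
            raise ConfigurationError(f"planted hit {eff.compound_id!r} not in the layout")
        effects.setdefault(eff.compound_id, []).append(eff)
    for cid in config.toxic_compounds:
        if cid not in known_compounds:
            raise ConfigurationError(f"toxic compound {cid!r} not in the layout")

    cell_rows = []
    map_rows = []
    truth_rows = []
    for plate in range(1, config.n_plates + 1):
        plate_id = f"P{plate:03d}"
        prng = substream(config.seed, "screen", plate)
        plate_surface = float(
            _lognormal_around_mean(prng, 1.0, config.plate_effect_sd, ())
        )
        plate_total = float(
            _lognormal_around_mean(prng, 1.0, config.plate_effect_sd, ())
        )
        for well in labels:
            role = config.control_layout.get(well, ROLE_COMPOUND)
            if role == ROLE_COMPOUND:
                cid = config.compound_id_for(plate, well)
                conc = config.compound_concentration_uM
            else:
                cid = "DMSO" if role == ROLE_NEG else "E115G"
                conc = 0.0
            map_rows.append(
                {"plate_id": plate_id, "well": well, "role": role,
                 "compound_id": cid, "concentration_uM": conc}
            )

            mean_surface = config.baseline_surface * plate_surface
            mean_total = config.baseline_total * plate_total
            if role == ROLE_POS:
                mean_surface *= config.pos_surface_factor
                mean_total *= config.pos_total_factor

            n_mean = config.n_cells_mean
            if role == ROLE_COMPOUND:
                for eff in effects.get(cid, []):
                    f = config.effect_factor(eff)
                    if eff.metric in ("surface", "ratio"):
                        mean_surface *= f
                    else:
                        mean_total *= f
                    truth_rows.append(
                        {"plate_id": plate_id, "well": well, "compound_id": cid,
                         "kind": "hit", "metric": eff.metric, "factor": f,
                         "mad_units": eff.mad_units}
                    )
                if cid in config.toxic_compounds:
                    mult = config.toxic_compounds[cid]
                    if mult < 0:
                        raise ConfigurationError("cell-count multiplier must be >= 0")
                    n_mean *= mult
                    truth_rows.append(
                        {"plate_id": plate_id, "well": well, "compound_id": cid,
                         "kind": "toxic", "metric": "cellcount", "factor": mult,
                         "mad_units": None}
                    )

            wrng = substream(config.seed, "screen", plate, well)
            if config.well_level_cv > 0:
                mean_surface *= float(_lognormal_around_mean(wrng, 1.0, config.well_level_cv, ()))
                mean_total *= float(_lognormal_around_mean(wrng, 1.0, config.well_level_cv, ()))
            if config.n_cells_dispersion is None:
                n_cells = int(wrng.poisson(n_mean))
            else:
                lam = wrng.gamma(config.n_cells_dispersion, n_mean / config.n_cells_dispersion)
                n_cells = int(wrng.poisson(lam))
            if n_cells == 0:
                continue
            surface = _lognormal_around_mean(wrng, mean_surface, config.cell_level_cv, n_cells)
            total = _lognormal_around_mean(wrng, mean_total, config.cell_level_cv, n_cells)
            for i in range(n_cells):
                cell_rows.append(
                    (plate_id, well, cid, f"{well}-{i:04d}", surface[i], total[i])
                )

    cells = pd.DataFrame(
        cell_rows,
        columns=["plate_id", "well", "compound_id", "cell_id", "surface_fiu", "total_fiu"],
    )
    plate_map = pd.DataFrame(map_rows)
    truth = pd.DataFrame(
        truth_rows,
        columns=["plate_id", "well", "compound_id", "kind", "metric", "factor", "mad_units"],
    )
    return cells, plate_map, truth
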