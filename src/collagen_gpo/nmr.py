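"""Two-state fast-exchange shift model and DQ-SQ peak prediction.

The X-position proline ring of a GPO triplet flips between endo and exo
puckers fast on the NMR timescale, so its observed ¹³Cγ isotropic shift
is the population-weighted average of the endo (23.8 ppm) and exo
(25.7 ppm) reference shifts:

    δ_obs = p_endo · δ_endo + (1 − p_endo) · δ_exo

Inverting this gives the endo population directly from an observed Cγ
shift.  Residues that precede an imino acid (the P of GPO precedes Hyp)
additionally show the *proline effect*: a 1–2 ppm reduction of their Cα,
Cβ and C′ shifts, which is what separates GPO from GPY proline signals
in a crowded spectrum.  In a ¹³C-¹³C double-quantum–single-quantum
(DQ-SQ) correlation spectrum each bonded carbon pair appears at a DQ
frequency equal to the sum of the two SQ shifts, so a full
C′-Cα-Cβ-Cγ-Cδ connectivity walk can be predicted from a shift table
alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from collagen_gpo.errors import InputError, ParameterError

logger = logging.getLogger(__name__)

#: reference Cγ shifts of the two pucker states (ppm)
DELTA_ENDO = 23.8
DELTA_EXO = 25.7

#: default magnitude of the proline effect (midpoint of the 1–2 ppm range)
PROLINE_EFFECT_PPM = 1.5
#: carbons the proline effect applies to
PROLINE_EFFECT_CARBONS = ("C", "CA", "CB")

#: the proline carbon connectivity walk, amide carbon first
PROLINE_WALK = (("C", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD"))

#: tolerance for observed shifts slightly outside the two-state range (ppm)
OBS_TOLERANCE = 0.2


@dataclass(frozen=True)
class TwoStateExchangeModel:
    """Endo/exo Cγ reference shifts for fast two-site exchange."""

    delta_endo: float = DELTA_ENDO
    delta_exo: float = DELTA_EXO
    nucleus: str = "CG"

    def __post_init__(self) -> None:
        if self.delta_endo == self.delta_exo:
            raise ParameterError("endo and exo reference shifts must differ")


def endo_fraction(
    delta_obs: float,
    model: TwoStateExchangeModel = TwoStateExchangeModel(),
    *,
    tol: float = OBS_TOLERANCE,
) -> tuple[float, bool]:
    """Endo population from an observed Cγ shift.

    Returns ``(p_endo, clamped)``: shifts within ``tol`` ppm outside the
    [δ_endo, δ_exo] interval are clamped into [0, 1] with ``clamped``
    set; shifts further out raise (they signal a wrong assignment).
    """
    lo = min(model.delta_endo, model.delta_exo)
    hi = max(model.delta_endo, model.delta_exo)
    if not lo - tol <= delta_obs <= hi + tol:
        raise ParameterError(
            f"observed shift {delta_obs} ppm outside two-state range "
            f"[{lo - tol:.2f}, {hi + tol:.2f}]"
        )
    p = (model.delta_exo - delta_obs) / (model.delta_exo - model.delta_endo)
    clamped = not 0.0 <= p <= 1.0
    if clamped:
        logger.warning("endo fraction %.4f clamped into [0, 1]", p)
    return float(np.clip(p, 0.0, 1.0)), clamped


def average_shift(
    p_endo: float, model: TwoStateExchangeModel = TwoStateExchangeModel()
) -> float:
    """Population-weighted average shift of a fast-flipping ring."""
    if not 0.0 <= p_endo <= 1.0:
        raise ParameterError(f"p_endo must be in [0, 1], got {p_endo}")
    return p_endo * model.delta_endo + (1.0 - p_endo) * model.delta_exo


@dataclass(frozen=True)
class ShiftTable:
    """Per-site ¹³C shifts.

    ``shifts`` maps ``(site_id, carbon)`` → ppm; ``context`` maps
    ``site_id`` → triplet context (``"GPO"`` or ``"GPY"``).  A flag
    records whether the proline effect has already been applied, to
    guard against double application.
    """

    shifts: Mapping[tuple[str, str], float]
    context: Mapping[str, str]
    proline_effect_applied: bool = False

    def __post_init__(self) -> None:
        for (site, carbon), ppm in self.shifts.items():
            if not 0.0 <= ppm <= 220.0:
                raise ParameterError(
                    f"shift {ppm} ppm at ({site}, {carbon}) outside 0–220 ppm"
                )

    def sites(self) -> list[str]:
        return sorted(self.context)

    def get(self, site: str, carbon: str) -> float | None:
        return self.shifts.get((site, carbon))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "site": site,
                "context": self.context.get(site, ""),
                "carbon": carbon,
                "shift_ppm": ppm,
            }
            for (site, carbon), ppm in sorted(self.shifts.items())
        ]
        return pd.DataFrame(rows, columns=["site", "context", "carbon", "shift_ppm"])

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            if self.proline_effect_applied:
                fh.write("# proline_effect_applied=true\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ShiftTable":
        path = Path(path)
        if not path.exists():
            raise InputError(f"shift table not found: {path}")
        applied = False
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    if "proline_effect_applied=true" in line:
                        applied = True
                else:
                    break
        df = pd.read_csv(path, sep="\t", comment="#")
        shifts = {
            (str(r.site), str(r.carbon)): float(r.shift_ppm)
            for r in df.itertuples()
        }
        context = {str(r.site): str(r.context) for r in df.itertuples()}
        return cls(shifts, context, proline_effect_applied=applied)


def apply_proline_effect(
    table: ShiftTable, *, effect_size: float = PROLINE_EFFECT_PPM
) -> ShiftTable:
    """Reduce Cα, Cβ and C′ shifts of residues preceding an imino acid
    (GPO context) by ``effect_size`` ppm; Cγ and Cδ are untouched.

    Values outside the literature 1–2 ppm range are warned about but
    still applied.  Re-applying to a table already carrying the effect
    raises, to guard against double application.
    """
    if table.proline_effect_applied:
        raise ParameterError("proline effect already applied to this table")
    if not 1.0 <= effect_size <= 2.0:
        logger.warning(
            "proline effect %.2f ppm outside the expected 1–2 ppm range",
            effect_size,
        )
    new_shifts = dict(table.shifts)
    for (site, carbon), ppm in table.shifts.items():
        if table.context.get(site) == "GPO" and carbon in PROLINE_EFFECT_CARBONS:
            new_shifts[(site, carbon)] = ppm - effect_size
    return replace(table, shifts=new_shifts, proline_effect_applied=True)


@dataclass(frozen=True)
class DqPeak:
    """One DQ-SQ correlation peak pair: the double-quantum frequency is
    the exact sum of the two single-quantum shifts."""

    site: str
    carbons: tuple[str, str]
    sq_pair: tuple[float, float]
    weight: float = 1.0

    @property
    def dq(self) -> float:
        return self.sq_pair[0] + self.sq_pair[1]


def predict_dq_peaks(
    table: ShiftTable,
    connectivity: Sequence[tuple[str, str]] = PROLINE_WALK,
) -> list[DqPeak]:
    """One peak per bonded carbon pair per site; pairs with a missing
    carbon are skipped and logged."""
    peaks: list[DqPeak] = []
    for site in table.sites():
        for c1, c2 in connectivity:
            s1, s2 = table.get(site, c1), table.get(site, c2)
            if s1 is None or s2 is None:
                logger.info("site %s: pair (%s, %s) missing a shift — skipped", site, c1, c2)
                continue
            peaks.append(DqPeak(site, (c1, c2), (s1, s2)))
    return peaks


def peaks_to_tsv(
    peaks: Sequence[DqPeak], path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    df = pd.DataFrame(
        {
            "site": [p.site for p in peaks],
            "carbon_1": [p.carbons[0] for p in peaks],
            "carbon_2": [p.carbons[1] for p in peaks],
            "sq_1": [p.sq_pair[0] for p in peaks],
            "sq_2": [p.sq_pair[1] for p in peaks],
            "dq": [p.dq for p in peaks],
            "weight": [p.weight for p in peaks],
        }
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


@dataclass(frozen=True)
class TripletCountSummary:
    """GPY (Y ≠ O) and GPO triplet counts over a triple helix."""

    n_gpy: int
    n_gpo: int

    @property
    def ratio(self) -> float:
        if self.n_gpo == 0:
            raise ParameterError("GPY:GPO ratio undefined: no GPO triplets")
        return self.n_gpy / self.n_gpo


def count_triplets(
    chains: Sequence[str], *, hydroxylated_y: bool = False
) -> TripletCountSummary:
    """Count GPO and GPY (X = P, Y ≠ O) triplets over chains already in
    triplet register (each chain read as consecutive 3-residue frames).

    With ``hydroxylated_y`` a Y-position P counts as Hyp, as in the
    conservation module's rule for database-encoded sequences.
    """
    n_gpo = n_gpy = 0
    for chain in chains:
        seq = chain.upper()
        for i in range(0, len(seq) - 2, 3):
            g, x, y = seq[i], seq[i + 1], seq[i + 2]
            if g != "G" or x != "P":
                continue
            if y == "O" or (hydroxylated_y and y == "P"):
                n_gpo += 1
            else:
                n_gpy += 1
    return TripletCountSummary(n_gpy=n_gpy, n_gpo=n_gpo)


def expected_intensity_ratio(counts: TripletCountSummary) -> tuple[float, float]:
    """Expected GPY:GPO signal intensity ratio from sequence counts.

    Returns ``(raw, rounded_to_1dp)``; with equal per-triplet signal the
    intensity ratio equals the triplet count ratio.
    """
    raw = counts.ratio
    return raw, round(raw, 1)


@dataclass(frozen=True)
class GridSpec:
    """Axes of a simulated 2D DQ-SQ intensity map (ppm)."""

    sq_min: float
    sq_max: float
    dq_min: float
    dq_max: float
    n_sq: int = 256
    n_dq: int = 256

    def __post_init__(self) -> None:
        if self.sq_min >= self.sq_max or self.dq_min >= self.dq_max:
            raise ParameterError("grid bounds must satisfy min < max")
        if self.n_sq < 2 or self.n_dq < 2:
            raise ParameterError("grid must have at least 2 points per axis")

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.linspace(self.sq_min, self.sq_max, self.n_sq),
            np.linspace(self.dq_min, self.dq_max, self.n_dq),
        )


def simulate_dqsq(
    peaks: Sequence[DqPeak], linewidth: float, grid: GridSpec
) -> np.ndarray:
    """Render peaks as a sum of 2D Gaussians on (SQ, DQ) axes.

    Each peak contributes at both of its SQ positions at the shared DQ
    frequency, normalised so its grid-integrated intensity is
    proportional to its weight.  ``linewidth`` is the Gaussian FWHM in
    ppm.  Returns an array of shape ``(n_dq, n_sq)``.
    """
    if linewidth <= 0:
        raise ParameterError(f"linewidth must be > 0, got {linewidth}")
    sq_ax, dq_ax = grid.axes()
    sigma = linewidth / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    out = np.zeros((grid.n_dq, grid.n_sq))
    norm = 1.0 / (2.0 * np.pi * sigma**2)
    for peak in peaks:
        for sq in peak.sq_pair:
            gx = np.exp(-0.5 * ((sq_ax - sq) / sigma) ** 2)
            gy = np.exp(-0.5 * ((dq_ax - peak.dq) / sigma) ** 2)
            out += peak.weight * norm * gy[:, None] * gx[None, :]
    return out


def grid_to_text(grid: np.ndarray, path: str | Path, spec: GridSpec) -> None:
    """Write the intensity grid as a plain matrix with an axes header."""
    with open(path, "w") as fh:
        fh.write(
            f"# sq {spec.sq_min} {spec.sq_max} {spec.n_sq} "
            f"dq {spec.dq_min} {spec.dq_max} {spec.n_dq}\n"
        )
        np.savetxt(fh, grid, fmt="%.6e")
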