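"""D-period fibril layout, overlap/hole zones and axial GPO bands.

Collagen molecules in a fibril are axially staggered by one D period
(~234 residues, 67 nm); five staggered molecules tile one period of the
structure.  Because the molecule length is not an integer multiple of D
(L = 4·D + r with r < D), each period splits into an *overlap* zone where
all five molecules contribute a residue and a *hole* (gap) zone where the
short fifth segment, D5, leaves a gap.  Within one molecule the three
chains are staggered by one residue with respect to each other.

This module lays out the residues of ``n_molecules`` D-staggered
molecules on an integer axial coordinate (0-based at molecule 1, leading
chain, residue 1), assigns overlap/hole zones, bins conserved GPO sites
axially, detects banded clusters of them, relates ligand binding sites to
the nearest band, and classifies each triplet locus by which chains carry
a conserved GPO there.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from collagen_gpo.conservation import ConservationProfile
from collagen_gpo.errors import ParameterError, RangeError

DEFAULT_D_PERIOD = 234
DEFAULT_N_MOLECULES = 5
DEFAULT_STAGGER = 1
DEFAULT_BAND_WINDOW = 9
DEFAULT_BAND_MIN_COUNT = 4

#: chain composition of a type I collagen molecule, in stagger order
#: (leading, middle, trailing)
DEFAULT_CHAIN_ORDER = ("alpha1", "alpha1", "alpha2")


@dataclass(frozen=True)
class FibrilLayout:
    """Axial coordinates of every residue of ``n_molecules`` staggered
    molecules.

    ``chains`` lists the chain type and helix length of the three chains
    of one molecule in stagger order; chain ``c`` (0-based) of molecule
    ``m`` (1-based) places residue ``r`` (1-based) at axial coordinate
    ``(m-1)*d_period + c*stagger + (r-1)``.
    """

    chains: tuple[tuple[str, int], ...]
    d_period: int = DEFAULT_D_PERIOD
    n_molecules: int = DEFAULT_N_MOLECULES
    stagger: int = DEFAULT_STAGGER

    def __post_init__(self) -> None:
        if self.d_period <= 0:
            raise ParameterError(f"d_period must be > 0, got {self.d_period}")
        if self.n_molecules < 1:
            raise ParameterError(
                f"n_molecules must be >= 1, got {self.n_molecules}"
            )
        lengths = [length for _, length in self.chains]
        if max(lengths) - min(lengths) > 3:
            raise ParameterError(
                "chain lengths must agree within one triplet, got "
                f"{lengths}"
            )

    def axial(self, molecule: int, chain_idx: int, residue: int) -> int:
        """Axial coordinate of one residue (molecule and residue 1-based)."""
        if not 1 <= molecule <= self.n_molecules:
            raise RangeError(f"molecule {molecule} outside 1..{self.n_molecules}")
        if not 0 <= chain_idx < len(self.chains):
            raise RangeError(f"chain index {chain_idx} outside molecule")
        length = self.chains[chain_idx][1]
        if not 1 <= residue <= length:
            raise RangeError(f"residue {residue} outside 1..{length}")
        return (molecule - 1) * self.d_period + chain_idx * self.stagger + (residue - 1)

    def molecule_span(self, molecule: int) -> tuple[int, int]:
        """Half-open axial interval covered by any chain of a molecule."""
        starts = [
            (molecule - 1) * self.d_period + c * self.stagger
            for c in range(len(self.chains))
        ]
        ends = [
            start + self.chains[c][1] for c, start in enumerate(starts)
        ]
        return min(starts), max(ends)

    @property
    def span(self) -> tuple[int, int]:
        """Half-open axial interval covered by the whole fibril segment."""
        spans = [self.molecule_span(m) for m in range(1, self.n_molecules + 1)]
        return min(s for s, _ in spans), max(e for _, e in spans)

    def coverage(self, axial_pos: int) -> int:
        """Number of molecules with at least one residue at ``axial_pos``."""
        count = 0
        for m in range(1, self.n_molecules + 1):
            start, end = self.molecule_span(m)
            if start <= axial_pos < end:
                count += 1
        return count


def build_layout(
    alpha1_length: int,
    alpha2_length: int,
    *,
    d_period: int = DEFAULT_D_PERIOD,
    n_molecules: int = DEFAULT_N_MOLECULES,
    stagger: int = DEFAULT_STAGGER,
    chain_order: Sequence[str] = DEFAULT_CHAIN_ORDER,
) -> FibrilLayout:
    """Lay out a heterotrimeric (2×α1 + 1×α2) fibril segment."""
    lengths = {"alpha1": alpha1_length, "alpha2": alpha2_length}
    unknown = set(chain_order) - set(lengths)
    if unknown:
        raise ParameterError(f"unknown chain types in chain_order: {unknown}")
    chains = tuple((ct, lengths[ct]) for ct in chain_order)
    return FibrilLayout(
        chains, d_period=d_period, n_molecules=n_molecules, stagger=stagger
    )


def zone_of(axial_pos: int, layout: FibrilLayout) -> str:
    """``"overlap"`` if every molecule has a residue at ``axial_pos``,
    else ``"hole"``; positions outside the fibril span raise."""
    start, end = layout.span
    if not start <= axial_pos < end:
        raise RangeError(f"axial position {axial_pos} outside fibril span [{start},{end})")
    return "overlap" if layout.coverage(axial_pos) == layout.n_molecules else "hole"


@dataclass(frozen=True)
class SitePlacement:
    """One conserved GPO site instance placed in the fibril."""

    molecule: int
    chain_idx: int
    chain_type: str
    triplet_index: int
    helix_pos: int
    axial_gly: int


@dataclass(frozen=True)
class AxialAnnotation:
    """One axial bin: its zone and the number of GPO residues in it."""

    axial_pos: int  # bin start
    zone: str
    gpo_count: int


@dataclass(frozen=True)
class GpoAxialProfile:
    """Binned axial distribution of conserved GPO residues, with the
    individual site placements retained for band membership."""

    layout: FibrilLayout
    bin_width: int
    bins: tuple[AxialAnnotation, ...]
    placements: tuple[SitePlacement, ...]

    def counts_by_position(self) -> dict[int, int]:
        """GPO residue count at every single axial position."""
        counts: dict[int, int] = {}
        for p in self.placements:
            for k in range(3):
                pos = p.axial_gly + k
                counts[pos] = counts.get(pos, 0) + 1
        return counts

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "axial_pos": [b.axial_pos for b in self.bins],
                "zone": [b.zone for b in self.bins],
                "gpo_count": [b.gpo_count for b in self.bins],
            }
        )


def gpo_axial_profile(
    layout: FibrilLayout,
    profiles: Mapping[str, ConservationProfile],
    *,
    bin_width: int = 3,
) -> GpoAxialProfile:
    """Place every conserved GPO site of every chain of every molecule
    and bin the resulting residues axially (default bin: one triplet)."""
    if bin_width < 1:
        raise ParameterError(f"bin_width must be >= 1, got {bin_width}")
    placements: list[SitePlacement] = []
    for m in range(1, layout.n_molecules + 1):
        for c, (chain_type, length) in enumerate(layout.chains):
            profile = profiles.get(chain_type)
            if profile is None:
                continue
            for t_idx, helix_pos in profile.conserved_sites():
                if helix_pos + 2 > length:
                    continue
                placements.append(
                    SitePlacement(
                        molecule=m,
                        chain_idx=c,
                        chain_type=chain_type,
                        triplet_index=t_idx,
                        helix_pos=helix_pos,
                        axial_gly=layout.axial(m, c, helix_pos),
                    )
                )
    counts: dict[int, int] = {}
    for p in placements:
        for k in range(3):
            pos = p.axial_gly + k
            counts[pos] = counts.get(pos, 0) + 1
    start, end = layout.span
    bins: list[AxialAnnotation] = []
    for b0 in range(start, end, bin_width):
        total = sum(counts.get(x, 0) for x in range(b0, min(b0 + bin_width, end)))
        bins.append(AxialAnnotation(b0, zone_of(b0, layout), total))
    return GpoAxialProfile(layout, bin_width, tuple(bins), tuple(placements))


@dataclass(frozen=True)
class GpoBand:
    """A banded cluster of GPO sites along an axis (axial or chain
    coordinates; half-open interval)."""

    start: int
    end: int
    members: tuple[SitePlacement, ...]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def centroid(self) -> float:
        return float((self.start + self.end - 1) / 2)


def _qualifying_band_intervals(
    counts: Mapping[int, int], window_w: int, min_count: int
) -> list[tuple[int, int]]:
    """Merge all width-``window_w`` windows holding >= ``min_count`` GPO
    residues into maximal half-open intervals, trimmed to occupied
    positions."""
    occupied = sorted(pos for pos, c in counts.items() if c > 0)
    if not occupied:
        return []
    qualifying: list[tuple[int, int]] = []
    for x in range(occupied[0] - window_w + 1, occupied[-1] + 1):
        total = sum(c for pos, c in counts.items() if x <= pos < x + window_w)
        if total >= min_count:
            qualifying.append((x, x + window_w))
    if not qualifying:
        return []
    merged: list[list[int]] = [list(qualifying[0])]
    for s, e in qualifying[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out: list[tuple[int, int]] = []
    for s, e in merged:
        inside = [pos for pos in occupied if s <= pos < e]
        if inside:
            out.append((inside[0], inside[-1] + 1))
    return out


def detect_bands(
    profile: GpoAxialProfile,
    *,
    window_w: int = DEFAULT_BAND_WINDOW,
    min_count: int = DEFAULT_BAND_MIN_COUNT,
) -> list[GpoBand]:
    """Detect axial GPO bands: maximal merges of sliding windows of
    ``window_w`` residues containing at least ``min_count`` GPO residues,
    sorted by start coordinate.  Every placement falls in at most one
    band because merged intervals are disjoint."""
    counts = profile.counts_by_position()
    intervals = _qualifying_band_intervals(counts, window_w, min_count)
    bands = []
    for s, e in intervals:
        members = tuple(
            p for p in profile.placements if s <= p.axial_gly < e or s <= p.axial_gly + 2 < e
        )
        bands.append(GpoBand(s, e, members))
    return bands


def detect_chain_bands(
    profile: ConservationProfile,
    *,
    window_w: int = DEFAULT_BAND_WINDOW,
    min_count: int = DEFAULT_BAND_MIN_COUNT,
) -> list[GpoBand]:
    """Band detection along a single chain in 1-based helix coordinates
    (one molecule, no stagger): used for binding-site flanks and for
    classifying mutations as in-band vs isolated."""
    placements = tuple(
        SitePlacement(1, 0, profile.chain_id, t, h, h)
        for t, h in profile.conserved_sites()
    )
    counts: dict[int, int] = {}
    for p in placements:
        for k in range(3):
            counts[p.helix_pos + k] = counts.get(p.helix_pos + k, 0) + 1
    intervals = _qualifying_band_intervals(counts, window_w, min_count)
    return [
        GpoBand(
            s,
            e,
            tuple(p for p in placements if s <= p.helix_pos < e or s <= p.helix_pos + 2 < e),
        )
        for s, e in intervals
    ]


@dataclass(frozen=True)
class BindingSiteAnnotation:
    """A ligand binding site on one chain, annotated with its nearest GPO
    band.  ``side`` is relative to the band centroid along the chain
    (N-terminal = site lies toward lower helix positions)."""

    name: str
    chain: str
    start: int  # 1-based helix positions, half-open interval [start, end)
    end: int
    nearest_band: GpoBand | None = None
    distance: float | None = None
    side: str | None = None


def site_flanks(
    site: BindingSiteAnnotation, bands: Sequence[GpoBand]
) -> BindingSiteAnnotation:
    """Annotate a binding site with its nearest band, the chain-coordinate
    distance to that band's centroid (0 when the intervals overlap) and
    which side of the band the site lies on."""
    if not bands:
        return replace(site, nearest_band=None, distance=None, side="no-band")

    def dist(band: GpoBand) -> float:
        if site.start < band.end and band.start < site.end:
            return 0.0
        c = band.centroid
        return min(abs(site.start - c), abs(site.end - 1 - c))

    nearest = min(bands, key=dist)
    d = dist(nearest)
    if d == 0.0:
        side = "overlapping"
    elif site.end - 1 < nearest.centroid:
        side = "N-terminal"
    else:
        side = "C-terminal"
    return replace(site, nearest_band=nearest, distance=d, side=side)


def chain_symmetry(
    triplet_index: int,
    profile_a1: ConservationProfile,
    profile_a2: ConservationProfile,
) -> str:
    """Classify a triplet locus by which chains are conserved-GPO there:
    ``all-chain``, ``alpha1-only``, ``alpha2-only`` or ``none``."""

    def conserved_at(profile: ConservationProfile) -> bool:
        try:
            i = profile.triplet_index.index(triplet_index)
        except ValueError:
            raise RangeError(
                f"triplet locus {triplet_index} outside profile "
                f"{profile.chain_id!r}"
            ) from None
        return profile.conserved[i]

    a1, a2 = conserved_at(profile_a1), conserved_at(profile_a2)
    if a1 and a2:
        return "all-chain"
    if a1:
        return "alpha1-only"
    if a2:
        return "alpha2-only"
    return "none"


def symmetry_by_zone(
    layout: FibrilLayout,
    profile_a1: ConservationProfile,
    profile_a2: ConservationProfile,
) -> pd.DataFrame:
    """Tabulate chain-symmetry classes of GPO loci per fibril zone.

    Each locus is assigned the zone of its Gly in the central molecule,
    which sits in the fully tiled region of the fibril segment.
    """
    mid = layout.n_molecules // 2 + 1
    shared = sorted(
        set(profile_a1.triplet_index) & set(profile_a2.triplet_index)
    )
    rows = []
    for t in shared:
        cls = chain_symmetry(t, profile_a1, profile_a2)
        if cls == "none":
            continue
        i = profile_a1.triplet_index.index(t)
        helix_pos = profile_a1.helix_pos[i]
        try:
            axial = layout.axial(mid, 0, helix_pos)
            zone = zone_of(axial, layout)
        except RangeError:
            continue
        rows.append({"triplet_index": t, "zone": zone, "symmetry": cls})
    df = pd.DataFrame(rows, columns=["triplet_index", "zone", "symmetry"])
    return (
        df.groupby(["zone", "symmetry"]).size().rename("n_loci").reset_index()
    )


def ascii_map(
    profile: GpoAxialProfile, *, mark: str = "O", empty: str = ".", gap: str = " "
) -> list[str]:
    """Text rendering of the fibril: one row per molecule, one character
    per axial bin; ``mark`` where the molecule carries conserved GPO
    residues in that bin, ``empty`` where it is present without GPO and
    ``gap`` where the molecule has no residue."""
    layout = profile.layout
    bw = profile.bin_width
    start, end = layout.span
    per_mol: dict[int, set[int]] = {m: set() for m in range(1, layout.n_molecules + 1)}
    for p in profile.placements:
        for k in range(3):
            per_mol[p.molecule].add(p.axial_gly + k)
    rows = []
    for m in range(1, layout.n_molecules + 1):
        ms, me = layout.molecule_span(m)
        row = []
        for b0 in range(start, end, bw):
            b1 = min(b0 + bw, end)
            if me <= b0 or ms >= b1:
                row.append(gap)
            elif any(x in per_mol[m] for x in range(b0, b1)):
                row.append(mark)
            else:
                row.append(empty)
        rows.append("".join(row))
    return rows
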