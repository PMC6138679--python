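"""Missense-variant overlap with conserved GPO triplets.

Mutation tables are TSV exports in the style of a ClinVar query:
one row per reported variant with its chain, 1-based helix position
(counted from the first Gly of the triple-helical domain), molecular
consequence, variation type, review-star count and associated condition.
Records are filtered to missense / single-nucleotide / at-least-one-star,
collapsed to unique substitutions, and intersected with the residue
positions (G, P or O) of conserved GPO triplets.  A triplet counts as
overlapping a mutation site if any one of its three residue positions
coincides with it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import pandas as pd

from collagen_gpo.conservation import ConservationProfile
from collagen_gpo.errors import InputError, ParameterError
from collagen_gpo.fibril import GpoBand

logger = logging.getLogger(__name__)

TSV_COLUMNS = [
    "chain",
    "helix_pos",
    "ref_aa",
    "alt_aa",
    "consequence",
    "variation_type",
    "review_stars",
    "condition",
]


@dataclass(frozen=True)
class MutationRecord:
    chain: str
    helix_pos: int
    ref_aa: str
    alt_aa: str
    consequence: str
    variation_type: str
    review_stars: int
    condition: str = ""

    def key(self) -> tuple[str, int, str, str]:
        """Identity of the substitution, used for duplicate collapse."""
        return (self.chain, self.helix_pos, self.ref_aa, self.alt_aa)


@dataclass(frozen=True)
class FilterCriteria:
    """Inclusion criteria applied to raw variant rows (defaults follow a
    missense / single-nucleotide / one-star-review ClinVar query)."""

    consequence: str = "missense"
    variation_type: str = "single nucleotide"
    min_stars: int = 1

    def accepts(self, rec: MutationRecord) -> bool:
        return (
            self.consequence in rec.consequence.lower()
            and rec.variation_type.lower() == self.variation_type
            and rec.review_stars >= self.min_stars
        )


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """Parse a mutation TSV; malformed rows are logged with their line
    number and skipped."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"mutation table not found: {path}")
    records: list[MutationRecord] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = set(TSV_COLUMNS) - set(header)
                if missing:
                    raise InputError(
                        f"mutation table missing columns: {sorted(missing)}"
                    )
                continue
            row = dict(zip(header, fields))
            try:
                rec = MutationRecord(
                    chain=row["chain"],
                    helix_pos=int(row["helix_pos"]),
                    ref_aa=row["ref_aa"],
                    alt_aa=row["alt_aa"],
                    consequence=row["consequence"],
                    variation_type=row["variation_type"],
                    review_stars=int(row["review_stars"]),
                    condition=row.get("condition", ""),
                )
                if rec.helix_pos < 1:
                    raise ValueError("helix_pos must be >= 1")
            except (KeyError, ValueError) as exc:
                logger.warning("%s line %d: skipping malformed row (%s)", path, lineno, exc)
                continue
            records.append(rec)
    if header is None:
        raise InputError(f"mutation table is empty: {path}")
    return records


def filter_mutations(
    records: Sequence[MutationRecord],
    criteria: FilterCriteria = FilterCriteria(),
) -> list[MutationRecord]:
    """Keep records meeting all criteria; collapse duplicates (same
    chain, position and substitution) to the first occurrence."""
    seen: set[tuple[str, int, str, str]] = set()
    out: list[MutationRecord] = []
    for rec in records:
        if not criteria.accepts(rec):
            continue
        if rec.key() in seen:
            continue
        seen.add(rec.key())
        out.append(rec)
    return out


@dataclass(frozen=True)
class OverlapResult:
    """Counts and percentages of mutation/conserved-GPO overlap.

    ``flags`` carries one label per in-range mutation: ``"overlapping"``
    before band classification, refined to ``"in-band"`` / ``"isolated"``
    by :func:`banded_vs_isolated`, or ``"non-GPO"``.
    """

    n_mutations: int
    n_overlapping: int
    n_conserved_gpo: int
    mutations: tuple[MutationRecord, ...]
    flags: tuple[str, ...]
    n_out_of_range: int = 0
    pct_overlapping: float | None = None
    pct_helix_conserved_gpo: float | None = None
    helix_length: int | None = None

    def overlapping_mutations(self) -> list[MutationRecord]:
        return [
            m
            for m, f in zip(self.mutations, self.flags)
            if f in ("overlapping", "in-band", "isolated")
        ]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [m.chain for m in self.mutations],
                "helix_pos": [m.helix_pos for m in self.mutations],
                "ref_aa": [m.ref_aa for m in self.mutations],
                "alt_aa": [m.alt_aa for m in self.mutations],
                "flag": self.flags,
            }
        )


def round1(x: float) -> float:
    """Round to 1 decimal, half away from zero (display convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def overlap_gpo(
    mutations: Sequence[MutationRecord],
    profile: ConservationProfile,
    *,
    helix_length: int | None = None,
) -> OverlapResult:
    """Intersect mutation positions with conserved GPO residue positions.

    A mutation overlaps iff its helix position equals the G, P or O
    position of any conserved triplet.  Positions beyond the consensus
    (``helix_length``, defaulting to the profile's extent) are flagged
    out of range, logged and excluded from the denominator.
    """
    max_pos = helix_length
    if max_pos is None and profile.helix_pos:
        max_pos = profile.helix_pos[-1] + 2
    gpo_positions = profile.conserved_helix_positions()
    kept: list[MutationRecord] = []
    flags: list[str] = []
    n_out = 0
    for m in mutations:
        if max_pos is not None and m.helix_pos > max_pos:
            logger.warning(
                "mutation %s:%d beyond consensus length %d — excluded",
                m.chain,
                m.helix_pos,
                max_pos,
            )
            n_out += 1
            continue
        kept.append(m)
        flags.append("overlapping" if m.helix_pos in gpo_positions else "non-GPO")
    return OverlapResult(
        n_mutations=len(kept),
        n_overlapping=sum(f == "overlapping" for f in flags),
        n_conserved_gpo=profile.n_conserved,
        mutations=tuple(kept),
        flags=tuple(flags),
        n_out_of_range=n_out,
    )


def overlap_stats(result: OverlapResult, helix_length: int) -> OverlapResult:
    """Fill display percentages (1-decimal, half-up rounding):

    * ``pct_overlapping`` = 100 · n_overlapping / n_mutations
    * ``pct_helix_conserved_gpo`` = 100 · 3·n_conserved_gpo / helix_length
    """
    if helix_length <= 0:
        raise ParameterError(f"helix_length must be > 0, got {helix_length}")
    pct_overlap = (
        round1(100 * result.n_overlapping / result.n_mutations)
        if result.n_mutations > 0
        else None
    )
    pct_helix = round1(100 * 3 * result.n_conserved_gpo / helix_length)
    return replace(
        result,
        pct_overlapping=pct_overlap,
        pct_helix_conserved_gpo=pct_helix,
        helix_length=helix_length,
    )


def banded_vs_isolated(
    result: OverlapResult,
    profile: ConservationProfile,
    bands: Sequence[GpoBand],
) -> tuple[int, int, OverlapResult]:
    """Split overlapping mutations by whether their GPO site sits in a
    band (chain-coordinate bands from :func:`fibril.detect_chain_bands`).

    Returns ``(n_in_band, n_isolated, refined_result)``; the two counts
    always sum to ``n_overlapping``.
    """
    banded_sites = {
        p.triplet_index for band in bands for p in band.members
    }
    site_of_pos: dict[int, int] = {}
    for t, h, flag in zip(profile.triplet_index, profile.helix_pos, profile.conserved):
        if flag:
            for k in range(3):
                site_of_pos[h + k] = t
    flags = list(result.flags)
    for i, (m, f) in enumerate(zip(result.mutations, result.flags)):
        if f not in ("overlapping", "in-band", "isolated"):
            continue
        t = site_of_pos.get(m.helix_pos)
        flags[i] = "in-band" if t in banded_sites else "isolated"
    refined = replace(result, flags=tuple(flags))
    n_in = sum(f == "in-band" for f in flags)
    n_iso = sum(f == "isolated" for f in flags)
    return n_in, n_iso, refined


def write_overlap_tsv(
    result: OverlapResult, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(f"# n_mutations={result.n_mutations}\n")
        fh.write(f"# n_overlapping={result.n_overlapping}\n")
        fh.write(f"# n_conserved_gpo={result.n_conserved_gpo}\n")
        if result.pct_overlapping is not None:
            fh.write(f"# pct_overlapping={result.pct_overlapping}\n")
        if result.pct_helix_conserved_gpo is not None:
            fh.write(
                f"# pct_helix_conserved_gpo={result.pct_helix_conserved_gpo}\n"
            )
        result.to_dataframe().to_csv(fh, sep="\t", index=False)
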