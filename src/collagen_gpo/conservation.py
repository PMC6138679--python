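"""GPO triplet conservation over pre-aligned collagen ortholog sets.

The triple-helical domain of a fibrillar collagen chain is an
uninterrupted run of G-X-Y triplets.  Given a multiple alignment of
orthologous chains (one representative per species, aligned elsewhere —
this module never aligns), we locate the shared triplet register on the
consensus, score each triplet site by the fraction of species that carry
an exact Gly-Pro-Hyp at it, and call sites conserved at a configurable
threshold (default 75%).

Deposited protein sequences encode hydroxyproline as plain ``P``; by
default a ``P`` in the Y position therefore counts as Hyp (``GPP`` ⇒ GPO).
Pass ``hydroxylated_y=False`` to require a literal ``O``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from collagen_gpo.errors import (
    AlignmentShapeError,
    InputError,
    NoRegisterError,
    ParameterError,
)

GAP = "-"
#: residue alphabet: the 20 canonical letters, O for hydroxyproline, X unknown
RESIDUES = set("ACDEFGHIKLMNPQRSTVWYOX")

DEFAULT_THRESHOLD = 0.75


@dataclass(frozen=True)
class AlignedChainSet:
    """One collagen chain's ortholog multiple alignment.

    ``records`` is an ordered list of ``(species_id, aligned_seq)``; all
    aligned sequences share the same column count and species ids are
    unique.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError("alignment contains no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"aligned records have unequal lengths: {sorted(lengths)}"
            )
        ids = [sid for sid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise InputError("species ids are not unique")

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    def column(self, j: int) -> list[str]:
        return [seq[j] for _, seq in self.records]

    def subset(self, species_ids: Iterable[str]) -> "AlignedChainSet":
        """Restrict to a subset of species (e.g. mammals only)."""
        wanted = set(species_ids)
        kept = tuple(r for r in self.records if r[0] in wanted)
        missing = wanted - {sid for sid, _ in kept}
        if missing:
            raise InputError(f"species not in alignment: {sorted(missing)}")
        return AlignedChainSet(kept)


@dataclass(frozen=True)
class ConsensusSequence:
    """Ungapped per-column modal sequence of an alignment.

    ``columns[i]`` is the 0-based alignment column that consensus residue
    ``i`` came from; ``modal_freq[i]`` is the fraction of records carrying
    the modal residue in that column.
    """

    chain_id: str
    residues: str
    modal_freq: tuple[float, ...]
    columns: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TripletFrame:
    """The G-X-Y reading frame of a consensus sequence.

    ``offset`` is the 0-based index of the first Gly of the first complete
    triplet; ``n_triplets`` the number of complete triplets from there.
    """

    offset: int
    n_triplets: int
    gly_fraction: float

    def __post_init__(self) -> None:
        if self.offset not in (0, 1, 2):
            raise ParameterError(f"offset must be 0, 1 or 2, got {self.offset}")


@dataclass(frozen=True)
class ConservationProfile:
    """Per-triplet-site GPO occurrence probabilities and conserved calls.

    ``helix_pos`` is the 1-based position of each site's Gly in the
    ungapped consensus.  ``conserved[s]`` is ``p_gpo[s] >= threshold``
    (closed bound).
    """

    chain_id: str
    triplet_index: tuple[int, ...]  # 1-based
    helix_pos: tuple[int, ...]
    p_gpo: tuple[float, ...]
    threshold: float = DEFAULT_THRESHOLD
    conserved: tuple[bool, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.conserved:
            object.__setattr__(
                self,
                "conserved",
                tuple(p >= self.threshold for p in self.p_gpo),
            )

    @property
    def n_sites(self) -> int:
        return len(self.triplet_index)

    @property
    def n_conserved(self) -> int:
        return sum(self.conserved)

    def conserved_helix_positions(self) -> set[int]:
        """All residue positions (G, X and Y) covered by conserved sites."""
        out: set[int] = set()
        for pos, flag in zip(self.helix_pos, self.conserved):
            if flag:
                out.update((pos, pos + 1, pos + 2))
        return out

    def conserved_sites(self) -> list[tuple[int, int]]:
        """(triplet_index, helix_pos) of every conserved site."""
        return [
            (t, h)
            for t, h, flag in zip(self.triplet_index, self.helix_pos, self.conserved)
            if flag
        ]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "triplet_index": self.triplet_index,
                "helix_pos": self.helix_pos,
                "p_gpo": self.p_gpo,
                "conserved": self.conserved,
            }
        )

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, chain_id: str = "") -> "ConservationProfile":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            chain_id=chain_id or str(path),
            triplet_index=tuple(int(v) for v in df["triplet_index"]),
            helix_pos=tuple(int(v) for v in df["helix_pos"]),
            p_gpo=tuple(float(v) for v in df["p_gpo"]),
            conserved=tuple(bool(v) for v in df["conserved"]),
        )


def read_alignment(path: str | Path) -> AlignedChainSet:
    """Read an aligned FASTA file (gap character ``-``).

    Sequences are upper-cased; ``O`` is accepted as hydroxyproline and
    ``X`` as an unknown residue (which never matches a triplet test).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"alignment file not found: {path}")
    records = [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if len(records) < 2:
        raise InputError(
            f"alignment must contain at least 2 records, found {len(records)}"
        )
    for sid, seq in records:
        bad = set(seq) - RESIDUES - {GAP}
        if bad:
            raise InputError(f"record {sid!r} contains invalid symbols {sorted(bad)}")
    return AlignedChainSet(tuple(records))


def consensus(aln: AlignedChainSet, chain_id: str = "consensus") -> ConsensusSequence:
    """Per-column modal residue, dropping columns where the gap wins.

    The modal residue of each column is the most frequent non-gap symbol;
    ties are broken alphabetically (so ``O`` beats ``P``).  A column is
    dropped only if gaps are strictly more frequent than every residue.
    """
    residues: list[str] = []
    freqs: list[float] = []
    cols: list[int] = []
    n = aln.n_records
    for j in range(aln.n_columns):
        counts = Counter(aln.column(j))
        gap_count = counts.pop(GAP, 0)
        if not counts:
            continue
        best = max(counts.values())
        if gap_count > best:
            continue
        modal = min(r for r, c in counts.items() if c == best)
        residues.append(modal)
        freqs.append(best / n)
        cols.append(j)
    return ConsensusSequence(chain_id, "".join(residues), tuple(freqs), tuple(cols))


def triplet_register(cons: ConsensusSequence | str) -> TripletFrame:
    """Find the G-X-Y register of a consensus sequence.

    The offset in {0, 1, 2} maximising the count of Gly at triplet
    position 1 wins; ties go to the smallest offset.  If even the best
    offset leaves Gly at fewer than half of the triplet-1 positions,
    there is no credible register and :class:`NoRegisterError` is raised.
    """
    seq = cons.residues if isinstance(cons, ConsensusSequence) else cons
    if len(seq) < 9:
        raise ParameterError(
            f"consensus too short for register detection: {len(seq)} < 9"
        )
    best_offset, best_count, best_frac = 0, -1, 0.0
    for off in (0, 1, 2):
        positions = range(off, len(seq) - 2, 3)
        n_pos = len(positions)
        if n_pos == 0:
            continue
        count = sum(1 for i in positions if seq[i] == "G")
        if count > best_count:
            best_offset, best_count, best_frac = off, count, count / n_pos
    if best_frac < 0.5:
        raise NoRegisterError(
            f"best offset {best_offset} places Gly at only "
            f"{100 * best_frac:.0f}% of triplet-1 positions"
        )
    n_triplets = (len(seq) - best_offset) // 3
    return TripletFrame(best_offset, n_triplets, best_frac)


def _y_matches(symbol: str, hydroxylated_y: bool) -> bool:
    return symbol == "O" or (hydroxylated_y and symbol == "P")


def gpo_conservation(
    aln: AlignedChainSet,
    frame: TripletFrame,
    cons: ConsensusSequence | None = None,
    *,
    hydroxylated_y: bool = True,
    threshold: float = DEFAULT_THRESHOLD,
    chain_id: str | None = None,
) -> ConservationProfile:
    """Probability of an exact GPO at every triplet site of the register.

    For each site, ``p_gpo`` is the fraction of aligned sequences whose
    three columns (mapped through the consensus' kept columns) read
    exactly G, P and a Y-match, with no gap anywhere in the triplet.
    Sites whose columns are all gap in a sequence simply do not count for
    that sequence, so an all-gap site scores 0.
    """
    if cons is None:
        cons = consensus(aln)
    if frame.offset + 3 * frame.n_triplets > len(cons):
        raise ParameterError("triplet frame does not fit the consensus")
    n = aln.n_records
    triplet_index: list[int] = []
    helix_pos: list[int] = []
    p_gpo: list[float] = []
    for s in range(frame.n_triplets):
        g = frame.offset + 3 * s
        c1, c2, c3 = cons.columns[g], cons.columns[g + 1], cons.columns[g + 2]
        count = 0
        for _, seq in aln.records:
            if (
                seq[c1] == "G"
                and seq[c2] == "P"
                and _y_matches(seq[c3], hydroxylated_y)
            ):
                count += 1
        triplet_index.append(s + 1)
        helix_pos.append(g + 1)
        p_gpo.append(count / n)
    return ConservationProfile(
        chain_id=chain_id or cons.chain_id,
        triplet_index=tuple(triplet_index),
        helix_pos=tuple(helix_pos),
        p_gpo=tuple(p_gpo),
        threshold=threshold,
    )


def classify_conserved(
    profile: ConservationProfile, threshold: float = DEFAULT_THRESHOLD
) -> ConservationProfile:
    """Re-call conserved sites at a new threshold (closed bound, p ≥ t)."""
    if not 0 < threshold <= 1:
        raise ParameterError(f"threshold must be in (0, 1], got {threshold}")
    return replace(
        profile,
        threshold=threshold,
        conserved=tuple(p >= threshold for p in profile.p_gpo),
    )


def consensus_gpo_sites(
    cons: ConsensusSequence,
    frame: TripletFrame,
    *,
    hydroxylated_y: bool = True,
) -> list[int]:
    """1-based triplet indices whose consensus triplet reads GPO."""
    out = []
    for s in range(frame.n_triplets):
        g = frame.offset + 3 * s
        if (
            cons.residues[g] == "G"
            and cons.residues[g + 1] == "P"
            and _y_matches(cons.residues[g + 2], hydroxylated_y)
        ):
            out.append(s + 1)
    return out


def write_consensus_fasta(
    cons: ConsensusSequence, path: str | Path, width: int = 60
) -> None:
    with open(path, "w") as fh:
        fh.write(f">{cons.chain_id}\n")
        for i in range(0, len(cons.residues), width):
            fh.write(cons.residues[i : i + width] + "\n")
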