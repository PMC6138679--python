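"""Seeded generators for every input the pipeline consumes.

Each generator emulates the statistical structure the analysis assumes —
an ortholog alignment with designed per-site GPO retention, a
ClinVar-style mutation table with planted overlap/filter-fail/duplicate
counts, an idealized triple-helix PDB with designed ring puckers, and a
¹³C shift table drawn from planted endo populations — and returns a
machine-readable *truth table* alongside the artifact, so every pipeline
stage has a ground truth to recover.

Reproducibility: one master seed; every artifact draws from its own
deterministic sub-stream (``numpy.random.default_rng([seed, stream])``),
so adding an output never shifts an existing one, and the same seed
yields byte-identical files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from collagen_gpo import geometry, nmr
from collagen_gpo.conservation import AlignedChainSet
from collagen_gpo.errors import ConfigError
from collagen_gpo.geometry import Residue, TripleHelixModel
from collagen_gpo.mutations import TSV_COLUMNS, MutationRecord
from collagen_gpo.nmr import ShiftTable, TwoStateExchangeModel, average_shift

# sub-stream indices per artifact
_STREAM_ORTHOLOGS = 0
_STREAM_MUTATIONS = 1
_STREAM_HELIX = 2
_STREAM_SHIFTS = 3

_X_ALPHABET = "PAELSKRQV"  # common collagen X-position residues
_Y_ALPHABET = "ARQKEGSTD"  # Y-position residues other than Hyp
_AA = "ACDEFGHIKLMNPQRSTVWY"


def _stream(seed: int, stream: int, salt: str = "") -> np.random.Generator:
    # crc32, not hash(): Python string hashing is randomised per process
    return np.random.default_rng([seed, stream, zlib.crc32(salt.encode())])


# ---------------------------------------------------------------------------
# ortholog alignments


@dataclass(frozen=True)
class OrthologConfig:
    """Designed ortholog set for one collagen chain.

    The template has ``n_triplets`` G-X-Y triplets with
    ``n_gpo_high + n_gpo_low`` designed GPO sites; the last
    ``terminal_gpo_run`` triplets form the conserved C-terminal GPO run.
    Per species each designed site retains its GPO with the site's
    retention probability; elsewhere residues substitute at ``sub_rate``
    and whole triplets delete (gap) at ``gap_rate``.
    """

    chain_id: str = "alpha1"
    n_species: int = 50
    n_triplets: int = 338
    n_gpo_high: int = 33
    n_gpo_low: int = 10
    retention_high: float = 0.95
    retention_low: float = 0.50
    terminal_gpo_run: int = 5
    sub_rate: float = 0.02
    gap_rate: float = 0.01
    encode_hyp_as_p: bool = True

    def __post_init__(self) -> None:
        for name in ("retention_high", "retention_low", "sub_rate", "gap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_gpo_high + self.n_gpo_low > self.n_triplets:
            raise ConfigError("more designed GPO sites than triplets")
        if self.terminal_gpo_run > self.n_gpo_high:
            raise ConfigError("terminal GPO run must fit within the high-retention sites")
        if self.n_species < 2:
            raise ConfigError("need at least 2 species")


def alpha1_config(**overrides) -> OrthologConfig:
    """α1(I)-like defaults: 43 GPO sites, 33 highly retained, C-terminal
    (GPO)5 run."""
    return replace(OrthologConfig(), **overrides)


def alpha2_config(**overrides) -> OrthologConfig:
    """α2(I)-like defaults: 33 GPO sites, 20 highly retained, C-terminal
    (GPO)4 run."""
    base = OrthologConfig(
        chain_id="alpha2",
        n_gpo_high=20,
        n_gpo_low=13,
        terminal_gpo_run=4,
    )
    return replace(base, **overrides)


def _y_symbol(cfg: OrthologConfig) -> str:
    return "P" if cfg.encode_hyp_as_p else "O"


def _design_template(
    cfg: OrthologConfig, rng: np.random.Generator
) -> tuple[list[tuple[str, str, str]], dict[int, float]]:
    """Template triplets and the designed per-site retention map
    (0-based triplet index → retention probability)."""
    n_sites = cfg.n_gpo_high + cfg.n_gpo_low
    terminal = list(range(cfg.n_triplets - cfg.terminal_gpo_run, cfg.n_triplets))
    interior_pool = list(range(cfg.n_triplets - cfg.terminal_gpo_run))
    interior = sorted(
        rng.choice(interior_pool, size=n_sites - cfg.terminal_gpo_run, replace=False)
    )
    gpo_sites = sorted(int(s) for s in interior) + terminal
    # high-retention sites: the terminal run plus a random subset of the rest
    non_terminal = [s for s in gpo_sites if s not in terminal]
    n_high_interior = cfg.n_gpo_high - cfg.terminal_gpo_run
    high = set(terminal) | {
        int(s) for s in rng.choice(non_terminal, size=n_high_interior, replace=False)
    }
    retention = {
        s: (cfg.retention_high if s in high else cfg.retention_low) for s in gpo_sites
    }
    y_sym = _y_symbol(cfg)
    template: list[tuple[str, str, str]] = []
    for t in range(cfg.n_triplets):
        if t in retention:
            template.append(("G", "P", y_sym))
        else:
            x = _X_ALPHABET[rng.integers(len(_X_ALPHABET))]
            y = _Y_ALPHABET[rng.integers(len(_Y_ALPHABET))]
            template.append(("G", x, y))
    return template, retention


def _is_gpo(triplet: Sequence[str], hydroxylated_y: bool = True) -> bool:
    g, x, y = triplet
    return g == "G" and x == "P" and (y == "O" or (hydroxylated_y and y == "P"))


def gen_ortholog_set(
    cfg: OrthologConfig, seed: int
) -> tuple[AlignedChainSet, pd.DataFrame]:
    """Generate an aligned ortholog set and its truth table.

    The truth table records, per triplet site, the designed retention and
    the *realised* per-site GPO count (tallied at generation time with
    the same matching rule the conservation module applies), so profile
    recovery is exact by construction.
    """
    rng = _stream(seed, _STREAM_ORTHOLOGS, cfg.chain_id)
    template, retention = _design_template(cfg, rng)
    species = [f"sp{i + 1:03d}" for i in range(cfg.n_species)]
    realised = np.zeros(cfg.n_triplets, dtype=int)
    records: list[tuple[str, str]] = []
    for sid in species:
        triplets: list[tuple[str, str, str]] = []
        for t, tpl in enumerate(template):
            if cfg.gap_rate > 0 and rng.random() < cfg.gap_rate:
                triplets.append(("-", "-", "-"))
                continue
            if t in retention:
                if rng.random() < retention[t]:
                    triplets.append(tpl)
                else:
                    # loss of the GPO: Y mutates to a non-imino residue
                    triplets.append(("G", "P", _Y_ALPHABET[rng.integers(len(_Y_ALPHABET))]))
            else:
                out = []
                for sym in tpl:
                    if rng.random() < cfg.sub_rate:
                        out.append(_AA[rng.integers(len(_AA))])
                    else:
                        out.append(sym)
                triplets.append(tuple(out))
        for t, trip in enumerate(triplets):
            if "-" not in trip and _is_gpo(trip, hydroxylated_y=True):
                realised[t] += 1
        records.append((sid, "".join("".join(trip) for trip in triplets)))
    truth = pd.DataFrame(
        {
            "triplet_index": np.arange(1, cfg.n_triplets + 1),
            "helix_pos": np.arange(0, cfg.n_triplets) * 3 + 1,
            "designed_gpo": [t in retention for t in range(cfg.n_triplets)],
            "retention": [retention.get(t, 0.0) for t in range(cfg.n_triplets)],
            "realised_gpo_count": realised,
            "n_species": cfg.n_species,
            "p_gpo_true": realised / cfg.n_species,
        }
    )
    return AlignedChainSet(tuple(records)), truth


def write_alignment_fasta(
    aln: AlignedChainSet, path: str | Path, width: int = 60
) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# mutation tables


@dataclass(frozen=True)
class MutationConfig:
    """Planted mutation-table composition.

    ``n_retained`` unique records pass the missense/single-nucleotide/
    one-star filter, of which ``n_overlapping`` sit on conserved-GPO
    residue positions; ``n_duplicates`` exact duplicates and
    ``n_filter_fail`` filter-failing rows are mixed in.
    """

    chain: str = "alpha1"
    n_retained: int = 95
    n_overlapping: int = 10
    n_filter_fail: int = 15
    n_duplicates: int = 10
    conditions: tuple[str, ...] = (
        "Osteogenesis imperfecta",
        "Ehlers-Danlos syndrome",
        "not provided",
    )

    def __post_init__(self) -> None:
        if self.n_overlapping > self.n_retained:
            raise ConfigError("n_overlapping cannot exceed n_retained")
        for name in ("n_retained", "n_filter_fail", "n_duplicates"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


def gen_mutation_table(
    cfg: MutationConfig,
    gpo_positions: set[int],
    helix_length: int,
    seed: int,
) -> tuple[list[MutationRecord], dict[str, int]]:
    """Generate a shuffled mutation table with planted composition.

    ``gpo_positions`` are the residue positions (G, P and O) of conserved
    GPO triplets on this chain; overlapping records are planted on them,
    non-overlapping ones strictly off them.
    """
    rng = _stream(seed, _STREAM_MUTATIONS, cfg.chain)
    gpo_sorted = sorted(p for p in gpo_positions if p <= helix_length)
    if cfg.n_overlapping > len(gpo_sorted):
        raise ConfigError(
            f"requested {cfg.n_overlapping} overlapping mutations but only "
            f"{len(gpo_sorted)} conserved GPO positions are available"
        )
    non_gpo = [p for p in range(1, helix_length + 1) if p not in gpo_positions]
    n_clean = cfg.n_retained - cfg.n_overlapping
    if n_clean > len(non_gpo):
        raise ConfigError("helix too short for the requested non-overlapping records")
    over_pos = [int(p) for p in rng.choice(gpo_sorted, size=cfg.n_overlapping, replace=False)]
    clean_pos = [int(p) for p in rng.choice(non_gpo, size=n_clean, replace=False)]

    def _sub(rng: np.random.Generator) -> tuple[str, str]:
        ref = _AA[rng.integers(len(_AA))]
        alt = _AA[rng.integers(len(_AA))]
        while alt == ref:
            alt = _AA[rng.integers(len(_AA))]
        return ref, alt

    def _record(pos: int) -> MutationRecord:
        ref, alt = _sub(rng)
        return MutationRecord(
            chain=cfg.chain,
            helix_pos=pos,
            ref_aa=ref,
            alt_aa=alt,
            consequence="missense variant",
            variation_type="single nucleotide",
            review_stars=int(rng.integers(1, 5)),
            condition=cfg.conditions[rng.integers(len(cfg.conditions))],
        )

    retained = [_record(p) for p in over_pos + clean_pos]
    rows = list(retained)
    # exact duplicates of already-retained substitutions
    for i in rng.choice(len(retained), size=min(cfg.n_duplicates, len(retained)), replace=False):
        rows.append(retained[int(i)])
    # filter-failing rows, cycling through the three failure modes
    fail_modes = ("synonymous", "zero-star", "deletion")
    for k in range(cfg.n_filter_fail):
        pos = int(rng.integers(1, helix_length + 1))
        ref, alt = _sub(rng)
        mode = fail_modes[k % len(fail_modes)]
        rows.append(
            MutationRecord(
                chain=cfg.chain,
                helix_pos=pos,
                ref_aa=ref,
                alt_aa=alt,
                consequence="synonymous variant" if mode == "synonymous" else "missense variant",
                variation_type="deletion" if mode == "deletion" else "single nucleotide",
                review_stars=0 if mode == "zero-star" else int(rng.integers(1, 5)),
                condition=cfg.conditions[int(rng.integers(len(cfg.conditions)))],
            )
        )
    order = rng.permutation(len(rows))
    shuffled = [rows[int(i)] for i in order]
    truth = {
        "n_rows": len(shuffled),
        "n_retained": len(retained),
        "n_overlapping": cfg.n_overlapping,
        "n_filter_fail": cfg.n_filter_fail,
        "n_duplicates": min(cfg.n_duplicates, len(retained)),
    }
    return shuffled, truth


def write_mutation_tsv(
    records: Sequence[MutationRecord], path: str | Path, seed: int | None = None
) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.chain,
                        str(r.helix_pos),
                        r.ref_aa,
                        r.alt_aa,
                        r.consequence,
                        r.variation_type,
                        str(r.review_stars),
                        r.condition,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# triple-helix models


@dataclass(frozen=True)
class HelixConfig:
    """Idealized triple-helix build specification.

    ``unit`` is the repeating triplet in chain order (default POG);
    ``pucker_design`` assigns proline ring states: ``all-endo``,
    ``all-exo``, ``alternating`` (prolines alternate along each chain) or
    ``random``; hydroxyproline rings always build *exo*, their strongly
    preferred state.
    """

    n_triplets: int = 12
    unit: str = "POG"
    pucker_design: str = "alternating"
    phi: float = geometry.PPII_PHI
    psi: float = geometry.PPII_PSI
    ring_displacement: float = 0.45
    chain_ids: tuple[str, str, str] = ("A", "B", "C")
    stagger_rise: float = 2.9  # Å axial shift per one-residue chain stagger
    # inter-chain spacing is generous: these models carry register,
    # connectivity and pucker, not real triple-helix packing, and the
    # bond graph must never see inter-chain contacts
    lateral_offset: float = 12.0  # Å between chain axes

    def __post_init__(self) -> None:
        if self.n_triplets < 2:
            raise ConfigError("need at least 2 triplets")
        if self.pucker_design not in ("all-endo", "all-exo", "alternating", "random"):
            raise ConfigError(f"unknown pucker design {self.pucker_design!r}")
        if set(self.unit.upper()) - set("GPOA"):
            raise ConfigError(f"unsupported residues in unit {self.unit!r}")


def gen_triple_helix(
    cfg: HelixConfig, seed: int
) -> tuple[TripleHelixModel, pd.DataFrame]:
    """Build a three-chain model at PPII dihedrals with designed puckers
    and a one-residue stagger; returns the model and a truth table of
    every ring state."""
    rng = _stream(seed, _STREAM_HELIX)
    sequence = list(cfg.unit.upper() * cfg.n_triplets)
    chains: dict[str, list[Residue]] = {}
    truth_rows = []
    for c_idx, cid in enumerate(cfg.chain_ids):
        puckers: dict[int, str] = {}
        pro_counter = 0
        for i, letter in enumerate(sequence, start=1):
            if letter == "P":
                if cfg.pucker_design == "all-endo":
                    state = "endo"
                elif cfg.pucker_design == "all-exo":
                    state = "exo"
                elif cfg.pucker_design == "alternating":
                    state = "endo" if pro_counter % 2 == 0 else "exo"
                else:
                    state = "endo" if rng.random() < 0.5 else "exo"
                puckers[i] = state
                pro_counter += 1
            elif letter == "O":
                puckers[i] = "exo"
        residues = geometry.build_chain(
            sequence,
            phi=cfg.phi,
            psi=cfg.psi,
            puckers=puckers,
            ring_displacement=cfg.ring_displacement,
        )
        # one-residue stagger along the chain axis plus a lateral offset
        start = residues[0].atoms["N"]
        end = residues[-1].atoms["C"]
        axis = end - start
        axis = axis / np.linalg.norm(axis)
        perp = np.cross(axis, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(axis, [0.0, 1.0, 0.0])
        perp = perp / np.linalg.norm(perp)
        shift = c_idx * cfg.stagger_rise * axis + c_idx * cfg.lateral_offset * perp
        for res in residues:
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + shift
        chains[cid] = residues
        for res in residues:
            if res.is_imino:
                truth_rows.append(
                    {
                        "chain": cid,
                        "res_id": res.res_id,
                        "res_name": res.name,
                        "pucker": puckers[res.res_id],
                    }
                )
    model = TripleHelixModel(chains)
    geometry.validate_model(model)
    truth = pd.DataFrame(truth_rows, columns=["chain", "res_id", "res_name", "pucker"])
    return model, truth


# ---------------------------------------------------------------------------
# shift tables


@dataclass(frozen=True)
class ShiftConfig:
    """Planted ¹³C shift-table specification.

    Cγ shifts are drawn as ``average_shift(p_endo) + N(0, noise_sd)``
    with per-site endo populations uniform in ``p_endo_range`` (kept away
    from 0/1 so clamping cannot bias recovery); the other carbons take
    base values plus the same noise.  GPO sites get the proline effect
    (−``effect_size`` ppm on C′, Cα, Cβ) applied at generation.
    """

    n_sites: int = 200
    frac_gpo: float = 0.5
    noise_sd: float = 0.05
    p_endo_range: tuple[float, float] = (0.2, 0.8)
    effect_size: float = nmr.PROLINE_EFFECT_PPM
    base_shifts: Mapping[str, float] = field(
        default_factory=lambda: {"C": 174.2, "CA": 61.2, "CB": 30.2, "CD": 49.8}
    )
    exchange: TwoStateExchangeModel = field(default_factory=TwoStateExchangeModel)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 <= self.frac_gpo <= 1.0:
            raise ConfigError("frac_gpo must be in [0, 1]")
        lo, hi = self.p_endo_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ConfigError("p_endo_range must be ordered within [0, 1]")


def gen_shift_table(cfg: ShiftConfig, seed: int) -> tuple[ShiftTable, pd.DataFrame]:
    """Generate a noisy shift table and the planted truth populations."""
    rng = _stream(seed, _STREAM_SHIFTS)
    shifts: dict[tuple[str, str], float] = {}
    context: dict[str, str] = {}
    rows = []
    n_gpo = int(round(cfg.frac_gpo * cfg.n_sites))
    for i in range(cfg.n_sites):
        site = f"site{i + 1:04d}"
        ctx = "GPO" if i < n_gpo else "GPY"
        context[site] = ctx
        lo, hi = cfg.p_endo_range
        p_endo = float(rng.uniform(lo, hi))
        cg_true = average_shift(p_endo, cfg.exchange)
        cg_obs = cg_true + float(rng.normal(0.0, cfg.noise_sd)) if cfg.noise_sd else cg_true
        shifts[(site, "CG")] = cg_obs
        for carbon, base in cfg.base_shifts.items():
            val = base
            if ctx == "GPO" and carbon in nmr.PROLINE_EFFECT_CARBONS:
                val -= cfg.effect_size
            if cfg.noise_sd:
                val += float(rng.normal(0.0, cfg.noise_sd))
            shifts[(site, carbon)] = val
        rows.append(
            {
                "site": site,
                "context": ctx,
                "p_endo_true": p_endo,
                "cg_true": cg_true,
                "cg_observed": cg_obs,
            }
        )
    table = ShiftTable(shifts, context, proline_effect_applied=True)
    truth = pd.DataFrame(
        rows, columns=["site", "context", "p_endo_true", "cg_true", "cg_observed"]
    )
    return table, truth


# ---------------------------------------------------------------------------
# truth-table I/O


def write_truth(df: pd.DataFrame, path: str | Path, seed: int) -> None:
    """Write a truth table as TSV with a ``# seed=`` provenance header."""
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
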