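"""End-to-end orchestration: synthetic fixtures → conservation →
fibril map → mutation overlap → pucker/conformer sampling → NMR
predictions, with a single summary table and a MANIFEST.

Every output is plain text (TSV / FASTA / PDB / ASCII map) with
``#``-prefixed provenance headers carrying the seed and stage
parameters; the whole run is deterministic under a fixed seed and
configuration, so reruns are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from collagen_gpo import __version__, conservation, fibril, geometry, mutations, nmr, synth

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a full pipeline run."""

    seed: int = 0
    out_dir: Path = Path("collagen_gpo_run")
    threshold: float = conservation.DEFAULT_THRESHOLD
    d_period: int = fibril.DEFAULT_D_PERIOD
    n_molecules: int = fibril.DEFAULT_N_MOLECULES
    stagger: int = fibril.DEFAULT_STAGGER
    band_window: int = fibril.DEFAULT_BAND_WINDOW
    band_min_count: int = fibril.DEFAULT_BAND_MIN_COUNT
    exchange: nmr.TwoStateExchangeModel = field(default_factory=nmr.TwoStateExchangeModel)
    orthologs_a1: synth.OrthologConfig = field(default_factory=synth.alpha1_config)
    orthologs_a2: synth.OrthologConfig = field(default_factory=synth.alpha2_config)
    mutations_a1: synth.MutationConfig = field(default_factory=synth.MutationConfig)
    mutations_a2: synth.MutationConfig = field(
        default_factory=lambda: synth.MutationConfig(
            chain="alpha2", n_retained=110, n_overlapping=9
        )
    )
    helix: synth.HelixConfig = field(default_factory=synth.HelixConfig)
    shifts: synth.ShiftConfig = field(default_factory=synth.ShiftConfig)
    n_perturbations: int = 200
    max_amplitude: float = 25.0

    def header(self, *extra: str) -> list[str]:
        return [
            f"collagen-gpo {__version__}",
            f"seed={self.seed}",
            *extra,
        ]


def run_all(config: RunConfig) -> dict[str, object]:
    """Run every stage on freshly generated synthetic fixtures.

    Writes stage outputs plus ``summary.tsv`` and ``MANIFEST`` under
    ``config.out_dir`` and returns the summary mapping.  On a stage
    failure the partial outputs are kept and the MANIFEST records the
    failure point before the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict[str, object] = {"seed": config.seed, "version": __version__}
    stage = "init"

    def done(name: str, *files: Path) -> None:
        for f in files:
            manifest.append(f"{name}\t{f.name}\tok")

    try:
        # --- synthetic ortholog sets and conservation ------------------
        stage = "conservation"
        profiles: dict[str, conservation.ConservationProfile] = {}
        consensi: dict[str, conservation.ConsensusSequence] = {}
        for chain, ocfg in (("alpha1", config.orthologs_a1), ("alpha2", config.orthologs_a2)):
            aln, truth = synth.gen_ortholog_set(ocfg, config.seed)
            aln_path = out / f"{chain}_alignment.fasta"
            synth.write_alignment_fasta(aln, aln_path)
            synth.write_truth(truth, out / f"{chain}_alignment_truth.tsv", config.seed)
            cons = conservation.consensus(aln, chain_id=chain)
            frame = conservation.triplet_register(cons)
            profile = conservation.gpo_conservation(
                aln, frame, cons, threshold=config.threshold, chain_id=chain
            )
            profiles[chain] = profile
            consensi[chain] = cons
            profile.to_tsv(
                out / f"{chain}_profile.tsv",
                config.header(f"chain={chain}", f"threshold={config.threshold}"),
            )
            conservation.write_consensus_fasta(cons, out / f"{chain}_consensus.fasta")
            summary[f"{chain}_n_triplets"] = frame.n_triplets
            summary[f"{chain}_n_gpo_consensus"] = len(
                conservation.consensus_gpo_sites(cons, frame)
            )
            summary[f"{chain}_n_conserved_gpo"] = profile.n_conserved
            done(stage, aln_path, out / f"{chain}_profile.tsv", out / f"{chain}_consensus.fasta")

        # --- fibril layout, zones, bands -------------------------------
        stage = "fibril-map"
        layout = fibril.build_layout(
            len(consensi["alpha1"].residues),
            len(consensi["alpha2"].residues),
            d_period=config.d_period,
            n_molecules=config.n_molecules,
            stagger=config.stagger,
        )
        axial = fibril.gpo_axial_profile(layout, profiles)
        axial_path = out / "fibril_axial_profile.tsv"
        with open(axial_path, "w") as fh:
            for line in config.header(f"d_period={config.d_period}"):
                fh.write(f"# {line}\n")
            axial.to_dataframe().to_csv(fh, sep="\t", index=False)
        bands = fibril.detect_bands(
            axial, window_w=config.band_window, min_count=config.band_min_count
        )
        bands_path = out / "fibril_bands.tsv"
        with open(bands_path, "w") as fh:
            for line in config.header(
                f"window_w={config.band_window}", f"min_count={config.band_min_count}"
            ):
                fh.write(f"# {line}\n")
            fh.write("band\taxial_start\taxial_end\tsize\n")
            for i, band in enumerate(bands, 1):
                fh.write(f"{i}\t{band.start}\t{band.end}\t{band.size}\n")
        map_path = out / "fibril_map.txt"
        with open(map_path, "w") as fh:
            for line in config.header():
                fh.write(f"# {line}\n")
            for row in fibril.ascii_map(axial):
                fh.write(row + "\n")
        zone_df = fibril.symmetry_by_zone(layout, profiles["alpha1"], profiles["alpha2"])
        zone_path = out / "fibril_zone_symmetry.tsv"
        with open(zone_path, "w") as fh:
            for line in config.header():
                fh.write(f"# {line}\n")
            zone_df.to_csv(fh, sep="\t", index=False)
        summary["n_axial_bands"] = len(bands)
        n_overlap = sum(1 for b in axial.bins if b.zone == "overlap")
        summary["n_overlap_bins"] = n_overlap
        summary["n_hole_bins"] = len(axial.bins) - n_overlap
        done(stage, axial_path, bands_path, map_path, zone_path)

        # --- mutation overlap ------------------------------------------
        stage = "mutmap"
        for chain, mcfg in (("alpha1", config.mutations_a1), ("alpha2", config.mutations_a2)):
            profile = profiles[chain]
            helix_length = len(consensi[chain].residues)
            records, truth = synth.gen_mutation_table(
                mcfg, profile.conserved_helix_positions(), helix_length, config.seed
            )
            mut_path = out / f"{chain}_mutations.tsv"
            synth.write_mutation_tsv(records, mut_path, seed=config.seed)
            retained = mutations.filter_mutations(records)
            result = mutations.overlap_gpo(retained, profile, helix_length=helix_length)
            result = mutations.overlap_stats(result, helix_length)
            chain_bands = fibril.detect_chain_bands(
                profile, window_w=config.band_window, min_count=config.band_min_count
            )
            n_in, n_iso, result = mutations.banded_vs_isolated(result, profile, chain_bands)
            overlap_path = out / f"{chain}_overlap.tsv"
            mutations.write_overlap_tsv(
                result, overlap_path, config.header(f"chain={chain}")
            )
            summary[f"{chain}_n_mutations"] = result.n_mutations
            summary[f"{chain}_n_overlapping"] = result.n_overlapping
            summary[f"{chain}_pct_overlapping"] = result.pct_overlapping
            summary[f"{chain}_pct_helix_conserved_gpo"] = result.pct_helix_conserved_gpo
            summary[f"{chain}_n_in_band"] = n_in
            summary[f"{chain}_n_isolated"] = n_iso
            summary[f"{chain}_truth_overlapping"] = truth["n_overlapping"]
            done(stage, mut_path, overlap_path)

        # --- triple helix, pucker, conformer sampling ------------------
        stage = "helix-geometry"
        model, helix_truth = synth.gen_triple_helix(config.helix, config.seed)
        pdb_path = out / "helix.pdb"
        geometry.write_structure(model, pdb_path)
        synth.write_truth(helix_truth, out / "helix_truth.tsv", config.seed)
        puckers = geometry.pucker_table(model)
        pucker_path = out / "pucker.tsv"
        with open(pucker_path, "w") as fh:
            for line in config.header():
                fh.write(f"# {line}\n")
            fh.write("chain\tres_id\tstate\tcg_displacement\n")
            for p in puckers:
                fh.write(f"{p.chain_id}\t{p.res_id}\t{p.state}\t{p.cg_displacement:.4f}\n")
        summary["n_prolines"] = len(puckers)
        summary["n_endo"] = sum(1 for p in puckers if p.state == "endo")
        summary["n_exo"] = sum(1 for p in puckers if p.state == "exo")

        trailing = config.helix.chain_ids[-1]
        # X-position proline of the 6th triplet of the trailing chain
        unit = config.helix.unit.upper()
        x_res = 5 * len(unit) + unit.index("P") + 1
        groups = geometry.standard_rotation_groups(model, trailing, x_res)
        spec = geometry.PerturbationSpec(
            groups=groups,
            max_amplitude=config.max_amplitude,
            n_perturbations=config.n_perturbations,
            seed=config.seed,
        )
        conformers = geometry.perturb(model, spec)
        tracked = [(trailing, x_res), (trailing, x_res + 1)]
        accepted = geometry.ppii_filter(conformers, tracked)
        conf_path = out / "conformers.tsv"
        with open(conf_path, "w") as fh:
            for line in config.header(
                f"n={config.n_perturbations}", f"amplitude={config.max_amplitude}"
            ):
                fh.write(f"# {line}\n")
            fh.write("conformer\tchain\tres_id\tphi\tpsi\tpucker\taccepted\n")
            accepted_idx = {c.index for c in accepted}
            for conf in conformers:
                for cid, rid in tracked:
                    rc = geometry.phi_psi(conf.model, cid, rid)
                    res = conf.model.residue(cid, rid)
                    state = (
                        geometry.ring_pucker(conf.model, cid, rid).state
                        if res.is_imino
                        else "-"
                    )
                    fh.write(
                        f"{conf.index}\t{cid}\t{rid}\t{rc.phi:.2f}\t{rc.psi:.2f}"
                        f"\t{state}\t{conf.index in accepted_idx}\n"
                    )
        summary["n_conformers"] = len(conformers)
        summary["n_accepted"] = len(accepted)
        if accepted:
            clusters = geometry.cluster_conformers(accepted, tracked)
            summary["n_unique_conformations"] = len(clusters)
        else:
            summary["n_unique_conformations"] = 0
        done(stage, pdb_path, pucker_path, conf_path)

        # --- NMR two-state model and DQ-SQ peaks -----------------------
        stage = "nmr"
        table, shift_truth = synth.gen_shift_table(config.shifts, config.seed)
        shift_path = out / "shifts.tsv"
        table.to_tsv(shift_path, config.header())
        synth.write_truth(shift_truth, out / "shifts_truth.tsv", config.seed)
        peaks = nmr.predict_dq_peaks(table)
        peaks_path = out / "dq_peaks.tsv"
        nmr.peaks_to_tsv(peaks, peaks_path, config.header())
        chains3 = [
            consensi["alpha1"].residues,
            consensi["alpha1"].residues,
            consensi["alpha2"].residues,
        ]
        counts = nmr.count_triplets(chains3, hydroxylated_y=True)
        raw, rounded = nmr.expected_intensity_ratio(counts)
        mean_p = sum(
            nmr.endo_fraction(table.get(site, "CG"), config.exchange)[0]
            for site in table.sites()
        ) / len(table.sites())
        summary["n_gpy"] = counts.n_gpy
        summary["n_gpo"] = counts.n_gpo
        summary["gpy_gpo_ratio"] = rounded
        summary["n_dq_peaks"] = len(peaks)
        summary["mean_endo_fraction"] = round(mean_p, 4)
        done(stage, shift_path, peaks_path)

    except Exception as exc:
        manifest.append(f"{stage}\t-\tFAILED: {exc}")
        _write_manifest(out, manifest, failed_stage=stage)
        raise

    # --- summary -------------------------------------------------------
    summary_path = out / "summary.tsv"
    with open(summary_path, "w") as fh:
        for line in config.header():
            fh.write(f"# {line}\n")
        fh.write("key\tvalue\n")
        for key, value in summary.items():
            fh.write(f"{key}\t{value}\n")
    manifest.append(f"summary\t{summary_path.name}\tok")
    _write_manifest(out, manifest)
    return summary


def _write_manifest(
    out: Path, entries: list[str], failed_stage: str | None = None
) -> None:
    with open(out / "MANIFEST", "w") as fh:
        fh.write("# stage\tfile\tstatus\n")
        for entry in entries:
            fh.write(entry + "\n")
        if failed_stage:
            fh.write(f"# pipeline FAILED at stage: {failed_stage}\n")
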