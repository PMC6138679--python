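"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from collagen_gpo import conservation, synth

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path


@pytest.fixture
def tiny_alignment():
    """8 species, 4 triplets: sites 1 and 3 are GPO in all, site 2 GPO in
    6/8 (p=0.75), site 4 never."""
    records = []
    for i in range(8):
        site2 = "GPP" if i < 6 else "GPA"
        records.append((f"sp{i}", "GPP" + site2 + "GPO" + "GAK"))
    return conservation.AlignedChainSet(tuple(records))


@pytest.fixture
def small_helix():
    """6-triplet POG helix with mixed designed puckers, plus its truth."""
    model, truth = synth.gen_triple_helix(
        synth.HelixConfig(n_triplets=6, pucker_design="alternating"), seed=11
    )
    return model, truth


def mean_plane_pucker_oracle(res, delta_min=0.02):
    """Cremer–Pople-style cross-check: least-squares mean plane of the
    five ring atoms, Cγ out-of-plane coordinate signed toward the
    carbonyl carbon.  Independent of the package's 3-atom-plane rule;
    the deadband is smaller because the mean plane tilts toward Cγ and
    shrinks its residual — only the side is comparable."""
    ring = np.array([res.atoms[a] for a in ("N", "CA", "CB", "CG", "CD")])
    center = ring.mean(axis=0)
    # smallest singular vector of the centred ring = plane normal
    _, _, vt = np.linalg.svd(ring - center)
    normal = vt[-1]
    if np.dot(res.atoms["C"] - center, normal) < 0:
        normal = -normal
    z_cg = float(np.dot(res.atoms["CG"] - center, normal))
    if z_cg > delta_min:
        return "endo"
    if z_cg < -delta_min:
        return "exo"
    return "planar"


def band_interval_oracle(counts, window_w, min_count):
    """Brute-force band oracle: the union of every qualifying window's
    positions, split into connected components, trimmed to occupied
    positions.  Returns half-open intervals."""
    occupied = sorted(p for p, c in counts.items() if c > 0)
    if not occupied:
        return []
    covered = set()
    for x in range(occupied[0] - window_w, occupied[-1] + window_w + 1):
        if sum(c for p, c in counts.items() if x <= p < x + window_w) >= min_count:
            covered.update(range(x, x + window_w))
    intervals = []
    run = []
    for p in sorted(covered):
        if run and p != run[-1] + 1:
            intervals.append(run)
            run = []
        run.append(p)
    if run:
        intervals.append(run)
    out = []
    for run in intervals:
        inside = [p for p in occupied if run[0] <= p <= run[-1]]
        if inside:
            out.append((inside[0], inside[-1] + 1))
    return out
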