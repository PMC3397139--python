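"""Synthetic proteomes with implanted modification motifs, and clustered
synthetic index collections.

The generator stands in for a curated PTM database: background sequences
are drawn i.i.d. from a residue distribution (uniform by default, which
keeps null-model behaviour sharp; UniProt-like composition is available),
and ``n_sites`` 9-mers are re-drawn from a position-specific motif and
annotated at their centres.  The motif ``strength`` mixes the motif
distribution with the background per position: 1.0 implants the motif
exactly, 0.0 leaves pure background (except the centre, which is always a
modifiable residue so annotations stay chemically plausible).  Implants are
non-overlapping and at least four residues from either terminus so labels
are unambiguous and windows unpadded.

``generate_index_collection`` emits a clustered set of synthetic 20-value
scales (well-separated cluster centres plus isotropic noise) together with
the cluster assignment whose medoids minimise summed intra-cluster
distance — enough structure to exercise the whole HQI selection path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .indices import ClusterAssignment, index_distance
from .io_formats import AMINO_ACIDS, AminoAcidIndex, ProteinRecord, SiteAnnotation

#: approximate residue frequencies of a vertebrate proteome
UNIPROT_LIKE_FREQS = {
    "A": 0.083, "C": 0.014, "D": 0.055, "E": 0.067, "F": 0.039,
    "G": 0.071, "H": 0.023, "I": 0.060, "K": 0.058, "L": 0.097,
    "M": 0.024, "N": 0.040, "P": 0.047, "Q": 0.039, "R": 0.055,
    "S": 0.066, "T": 0.054, "V": 0.069, "W": 0.011, "Y": 0.029,
}


@dataclass(frozen=True)
class MotifSpec:
    """A width-9 position-specific motif mixed with background at
    ``strength``; the centre distribution is supported only on the
    modifiable (target) residues."""

    position_dists: tuple[dict[str, float], ...]
    strength: float

    def __post_init__(self) -> None:
        if len(self.position_dists) != 9:
            raise ValueError("motif must define 9 position distributions")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")
        for i, dist in enumerate(self.position_dists):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"motif position {i}: probabilities sum to {total}"
                )
            bad = set(dist) - set(AMINO_ACIDS)
            if bad:
                raise ValueError(f"motif position {i}: unknown residues {bad}")

    @property
    def target_residues(self) -> set[str]:
        return {r for r, p in self.position_dists[4].items() if p > 0}


def kinase_like_motif(strength: float = 0.9) -> MotifSpec:
    """A basophilic serine/threonine motif (R/K at -3/-2, P/G/A at +1,
    hydrophobic at +3) reminiscent of basophilic kinase substrates."""
    uniform = {aa: 1.0 / 20 for aa in AMINO_ACIDS}
    basic = {"R": 0.5, "K": 0.5}
    return MotifSpec(
        position_dists=(
            uniform,
            basic,
            basic,
            uniform,
            {"S": 0.6, "T": 0.4},
            {"P": 0.5, "G": 0.25, "A": 0.25},
            uniform,
            {"L": 0.5, "I": 0.25, "V": 0.25},
            uniform,
        ),
        strength=strength,
    )


@dataclass(frozen=True)
class SynthConfig:
    """Proteome-generation settings: number and length of proteins, number
    of implanted sites, background composition, motif and seed."""

    n_proteins: int = 100
    mean_length: int = 300
    n_sites: int = 500
    motif: MotifSpec = field(default_factory=kinase_like_motif)
    background: dict[str, float] | None = None  # None = uniform over 20
    ptm_type: str = "Phospho_synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites > self.n_proteins * self.mean_length // 9:
            raise ValueError(
                f"{self.n_sites} non-overlapping 9-mer implants cannot fit in "
                f"{self.n_proteins} proteins of mean length {self.mean_length}"
            )


def generate_proteome(
    config: SynthConfig,
) -> tuple[list[ProteinRecord], list[SiteAnnotation]]:
    """Draw a background proteome and implant ``n_sites`` motif 9-mers.

    Implant centres are chosen uniformly at least 4 residues from either
    terminus and non-overlapping within a protein; the surrounding 9-mer is
    re-drawn position by position, taking the motif distribution with
    probability ``strength`` (always, at the centre) and background
    otherwise.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    residues = np.array(list(AMINO_ACIDS))
    if config.background is None:
        bg = np.full(20, 1.0 / 20)
    else:
        bg = np.array([config.background[aa] for aa in AMINO_ACIDS])
        bg = bg / bg.sum()

    lo = max(9, int(round(config.mean_length * 0.8)))
    hi = int(round(config.mean_length * 1.2))
    lengths = rng.integers(lo, hi + 1, size=config.n_proteins)
    sequences = [
        rng.choice(residues, size=length, p=bg) for length in lengths
    ]

    # place non-overlapping implant centres, >= 4 residues from termini
    taken: dict[int, list[int]] = {i: [] for i in range(config.n_proteins)}
    placements: list[tuple[int, int]] = []  # (protein index, 0-based centre)
    max_attempts = 200 * config.n_sites
    attempts = 0
    while len(placements) < config.n_sites:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {config.n_sites} non-overlapping implants "
                f"after {max_attempts} attempts"
            )
        p = int(rng.integers(config.n_proteins))
        length = lengths[p]
        c = int(rng.integers(4, length - 4))
        if any(abs(c - prev) < 9 for prev in taken[p]):
            continue
        taken[p].append(c)
        placements.append((p, c))

    motif = config.motif
    dists = []
    for offset, dist in enumerate(motif.position_dists):
        keys = np.array(sorted(dist))
        probs = np.array([dist[k] for k in sorted(dist)])
        dists.append((keys, probs))
    for p, c in placements:
        seq = sequences[p]
        for offset in range(9):
            keys, probs = dists[offset]
            from_motif = offset == 4 or rng.random() < motif.strength
            if from_motif:
                seq[c - 4 + offset] = rng.choice(keys, p=probs)
            else:
                seq[c - 4 + offset] = rng.choice(residues, p=bg)

    proteins = [
        ProteinRecord(id=f"SYNP{i:04d}", sequence="".join(seq))
        for i, seq in enumerate(sequences)
    ]
    annotations = [
        SiteAnnotation(f"SYNP{p:04d}", c + 1, config.ptm_type)
        for p, c in sorted(placements)
    ]
    return proteins, annotations


def generate_index_collection(
    n_clusters: int = 8,
    members_per_cluster: int = 5,
    spread: float = 0.5,
    seed: int = 0,
) -> tuple[list[AminoAcidIndex], ClusterAssignment]:
    """A clustered synthetic index collection.

    Cluster centres are drawn i.i.d. standard normal scaled well apart
    (sd 3) in 20-dimensional value space; members add isotropic noise of sd
    ``spread``.  The medoid of each cluster minimises summed unnormalised
    Euclidean distance to its co-members (accession breaks exact ties, so a
    zero-spread cluster has a deterministic medoid).
    """
    if members_per_cluster < 5:
        raise ValueError("members_per_cluster must be >= 5 to support tier 5")
    rng = np.random.default_rng(seed)
    indices: list[AminoAcidIndex] = []
    cluster_of: dict[str, int] = {}
    medoid_of: dict[int, str] = {}
    for cid in range(1, n_clusters + 1):
        center = rng.normal(0.0, 3.0, size=20)
        accs = []
        for m in range(members_per_cluster):
            values = center + rng.normal(0.0, spread, size=20)
            acc = f"SYN{cid:02d}{m:02d}001"
            accs.append(acc)
            indices.append(
                AminoAcidIndex(
                    accession=acc,
                    description=f"synthetic index, cluster {cid}",
                    values=dict(zip(AMINO_ACIDS, map(float, values))),
                )
            )
            cluster_of[acc] = cid
        by_acc = {i.accession: i for i in indices}
        medoid_of[cid] = min(
            accs,
            key=lambda a: (
                sum(
                    index_distance(by_acc[a], by_acc[b], normalized=False)
                    for b in accs
                ),
                a,
            ),
        )
    return indices, ClusterAssignment(cluster_of=cluster_of, medoid_of=medoid_of)
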