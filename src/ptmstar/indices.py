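"""High-quality index (HQI) selection from clustered amino-acid index collections.

The AAindex1 database holds hundreds of 20-value physico-chemical scales.
Given a clustering of those scales (eight clusters in the reference
clustering shipped with this package), three nested "high quality index"
tiers are defined per cluster:

* tier 1 — the cluster medoid only (HQI-8 over eight clusters);
* tier 3 — the medoid plus the two members farthest from it, which add
  diversity (HQI-24);
* tier 5 — the tier-3 members plus the two non-medoid members nearest to the
  medoid, which reinforce the medoid's property (HQI-40).

Farthest/nearest geometry uses Euclidean distance over z-scored 20-value
vectors by default; ties are broken by accession so selection is fully
deterministic.  The clustering itself is an input (cluster-assignment TSV),
not computed here.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .io_formats import AMINO_ACIDS, AminoAcidIndex

logger = logging.getLogger(__name__)

#: tier -> number of indices taken per cluster
VALID_TIERS = (1, 3, 5)


@dataclass(frozen=True)
class ClusterAssignment:
    """Cluster membership and medoids for an index collection.

    ``cluster_of`` maps accession -> cluster id; ``medoid_of`` maps cluster
    id -> the accession of its medoid.  Every cluster has exactly one medoid
    and the medoid belongs to its own cluster.
    """

    cluster_of: dict[str, int]
    medoid_of: dict[int, str]

    def __post_init__(self) -> None:
        cluster_ids = set(self.cluster_of.values())
        if set(self.medoid_of) != cluster_ids:
            raise ValueError(
                "every cluster must have exactly one medoid: clusters "
                f"{sorted(cluster_ids)} vs medoids for {sorted(self.medoid_of)}"
            )
        for cid, acc in self.medoid_of.items():
            if self.cluster_of.get(acc) != cid:
                raise ValueError(
                    f"medoid {acc!r} of cluster {cid} is not a member of it"
                )

    def members(self, cluster_id: int) -> list[str]:
        return sorted(
            acc for acc, cid in self.cluster_of.items() if cid == cluster_id
        )

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(self.medoid_of)


@dataclass(frozen=True)
class IndexSet:
    """An ordered, named subset of amino-acid indices (one HQI tier)."""

    name: str
    members: tuple[AminoAcidIndex, ...]

    def __post_init__(self) -> None:
        accs = [m.accession for m in self.members]
        if len(set(accs)) != len(accs):
            raise ValueError(f"index set {self.name}: duplicate accessions")

    @property
    def dimension(self) -> int:
        return len(self.members)

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(m.accession for m in self.members)


def make_index_set(
    name: str,
    collection: Sequence[AminoAcidIndex],
    accessions: Sequence[str] | None = None,
) -> IndexSet:
    """Build an IndexSet from a collection, optionally restricted/ordered
    by an explicit accession list (used for config-defined sets such as the
    legacy 10-index descriptor)."""
    by_acc = {idx.accession: idx for idx in collection}
    if accessions is None:
        members = tuple(collection)
    else:
        missing = [a for a in accessions if a not in by_acc]
        if missing:
            raise KeyError(f"index set {name}: accessions not found: {missing}")
        members = tuple(by_acc[a] for a in accessions)
    return IndexSet(name=name, members=members)


# ---------------------------------------------------------------------------
# distances and selection


def index_distance(
    a: AminoAcidIndex, b: AminoAcidIndex, normalized: bool = True
) -> float:
    """Euclidean distance between two indices over their 20-value vectors.

    With ``normalized`` each index is first z-scored across its own 20
    values, so scales with large raw magnitudes do not dominate; a constant
    index z-scores to the zero vector.
    """
    va = np.array([a.values[r] for r in AMINO_ACIDS], dtype=float)
    vb = np.array([b.values[r] for r in AMINO_ACIDS], dtype=float)
    if normalized:
        va = _zscore(va)
        vb = _zscore(vb)
    return float(np.linalg.norm(va - vb))


def _zscore(v: np.ndarray) -> np.ndarray:
    if v.max() == v.min():  # constant scale: no information, zero vector
        return np.zeros_like(v)
    return (v - v.mean()) / v.std()


def select_hqi(
    collection: Sequence[AminoAcidIndex],
    clusters: ClusterAssignment,
    tier: int,
    normalized: bool = True,
) -> IndexSet:
    """Select the HQI tier (1, 3 or 5 indices per cluster) from a clustered
    collection.

    Tier 1 returns the medoids; tier 3 adds the two members farthest from
    each medoid; tier 5 further adds the two non-medoid members nearest to
    each medoid.  Member order is cluster id ascending, then medoid,
    farthest pair (decreasing distance), nearest pair (increasing distance);
    equal distances are broken by accession (logged).  Indices without a
    cluster assignment are ignored.
    """
    if tier not in VALID_TIERS:
        raise ValueError(f"tier must be one of {VALID_TIERS}, got {tier}")
    by_acc = {idx.accession: idx for idx in collection}
    missing = [a for a in clusters.cluster_of if a not in by_acc]
    if missing:
        raise KeyError(f"clustered accessions not in collection: {missing}")

    chosen: list[AminoAcidIndex] = []
    for cid in clusters.cluster_ids:
        members = clusters.members(cid)
        if len(members) < tier:
            raise ValueError(
                f"cluster {cid} has {len(members)} members; tier {tier} "
                f"needs at least {tier}"
            )
        medoid_acc = clusters.medoid_of[cid]
        chosen.append(by_acc[medoid_acc])
        if tier == 1:
            continue
        others = [a for a in members if a != medoid_acc]
        dists = {
            a: index_distance(by_acc[medoid_acc], by_acc[a], normalized)
            for a in others
        }
        if len(set(dists.values())) < len(dists):
            logger.info(
                "select_hqi: distance ties in cluster %d broken by accession",
                cid,
            )
        # farthest two: distance descending, accession ascending on ties
        farthest = sorted(others, key=lambda a: (-dists[a], a))[:2]
        chosen.extend(by_acc[a] for a in farthest)
        if tier == 5:
            remaining = [a for a in others if a not in farthest]
            nearest = sorted(remaining, key=lambda a: (dists[a], a))[:2]
            chosen.extend(by_acc[a] for a in nearest)

    n = tier * len(clusters.cluster_ids)
    name = f"HQI-{n}"
    return IndexSet(name=name, members=tuple(chosen))


# ---------------------------------------------------------------------------
# cluster-assignment and HQI config I/O


def read_cluster_assignments(path: str | Path) -> ClusterAssignment:
    """Read a cluster-assignment TSV (accession, cluster_id, is_medoid)."""
    cluster_of: dict[str, int] = {}
    medoid_of: dict[int, str] = {}
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            acc, cid_str, medoid_str = (c.strip() for c in row[:3])
            if lineno == 1 and not cid_str.lstrip("-").isdigit():
                continue  # header
            cid = int(cid_str)
            if acc in cluster_of:
                raise ValueError(f"{path}:{lineno}: duplicate accession {acc}")
            cluster_of[acc] = cid
            if medoid_str.lower() in ("1", "true", "yes"):
                if cid in medoid_of:
                    raise ValueError(
                        f"{path}:{lineno}: cluster {cid} has two medoids"
                    )
                medoid_of[cid] = acc
    return ClusterAssignment(cluster_of=cluster_of, medoid_of=medoid_of)


def write_cluster_assignments(
    clusters: ClusterAssignment, path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["accession", "cluster_id", "is_medoid"])
        for acc in sorted(clusters.cluster_of):
            cid = clusters.cluster_of[acc]
            writer.writerow([acc, cid, int(clusters.medoid_of[cid] == acc)])


def load_hqi_config(path: str | Path | None = None) -> dict[str, list[str]]:
    """Load the HQI accession lists from a YAML config.

    Without a path, the packaged reference config is used; it carries the
    eight published cluster-medoid accessions (the HQI-8 tier).  Returns a
    mapping tier name -> accession list.
    """
    if path is None:
        text = (
            resources.files("ptmstar").joinpath("data/hqi_sets.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    config = yaml.safe_load(text)
    if not isinstance(config, dict):
        raise ValueError("HQI config must be a mapping of tier name -> list")
    return {str(k): [str(a) for a in v] for k, v in config.items()}
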