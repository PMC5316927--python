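"""Synthetic-data generators with known ground truth.

Every pipeline stage is exercised against data produced here: genomes with
planted repeats that are either collapsed (n copies in the true genome, fewer
in the assembly) or retained (equal copies in both), uniform-depth single-end
reads, codon-sequence pairs diverged to a target Ks, synteny anchor sets with
planted 1x/2x/3x ploidy structure, and modal-Ks observation tables generated
from an event tree with known branch lengths.  Each generator is
deterministic for a fixed seed and returns a manifest the tests recompute
against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chronology as chron
from ._seq import BASES, SENSE_CODONS, STOP_CODONS, random_dna, revcomp
from .ks import CODON_AA, jukes_cantor, syn_sites


class SizingError(ValueError):
    """Requested planted features overlap or exceed the genome length."""


# ---------------------------------------------------------------------------
# Genomes with planted collapsed / retained repeats
# ---------------------------------------------------------------------------


@dataclass
class FeatureSpec:
    """Request for one planted repeat family.

    kind "collapsed": copies_in_truth >= 2 copies exist in the true genome but
    only copies_in_assembly (< truth) were assembled.  kind
    "repeated_non_collapsed": all copies are present in both.  identity < 1
    introduces random substitutions into the non-template copies.
    """

    kind: str
    unit_length: int
    copies_in_truth: int
    copies_in_assembly: int | None = None
    identity: float = 1.0

    def __post_init__(self):
        if self.kind not in ("collapsed", "repeated_non_collapsed"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.copies_in_assembly is None:
            self.copies_in_assembly = (
                1 if self.kind == "collapsed" else self.copies_in_truth
            )
        if self.copies_in_truth < 2:
            raise ValueError("planted features need copies_in_truth >= 2")
        if self.kind == "collapsed" and self.copies_in_assembly >= self.copies_in_truth:
            raise ValueError("collapsed features need assembly copies < truth copies")
        if (
            self.kind == "repeated_non_collapsed"
            and self.copies_in_assembly != self.copies_in_truth
        ):
            raise ValueError("retained repeats need equal copies in truth and assembly")


@dataclass
class PlantedFeature:
    kind: str
    unit_length: int
    copies_in_truth: int
    copies_in_assembly: int
    assembly_coords: list[tuple[int, int]]  # half-open, within the assembly
    truth_coords: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class GenomeTruth:
    """Synthetic assembly plus the true genome reads are drawn from."""

    assembly: dict[str, str]
    truth: dict[str, str]
    features: list[PlantedFeature]
    seed: int

    @property
    def assembly_length(self) -> int:
        return sum(len(s) for s in self.assembly.values())

    @property
    def truth_length(self) -> int:
        return sum(len(s) for s in self.truth.values())

    def manifest(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.features):
            for start, end in f.assembly_coords:
                rows.append(
                    {
                        "feature": i,
                        "kind": f.kind,
                        "unit_length": f.unit_length,
                        "copies_in_truth": f.copies_in_truth,
                        "copies_in_assembly": f.copies_in_assembly,
                        "start": start,
                        "end": end,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "feature",
                "kind",
                "unit_length",
                "copies_in_truth",
                "copies_in_assembly",
                "start",
                "end",
            ],
        )


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        out[i] = BASES[(BASES.index(out[i]) + rng.integers(1, 4)) % 4]
    return "".join(out)


def simulate_genome(
    length: int,
    features: list[FeatureSpec] | None = None,
    gc: float = 0.5,
    seed: int = 0,
    name: str = "chr1",
) -> GenomeTruth:
    """One-sequence synthetic assembly with planted repeat features.

    The assembly has exactly `length` bases; the true genome additionally
    carries the unassembled copies of collapsed features, so
    truth_length == length + sum (copies_in_truth - copies_in_assembly) *
    unit_length.
    """
    features = list(features or [])
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    total_planted = sum(f.unit_length * f.copies_in_assembly for f in features)
    if features and length < 10 * sum(f.unit_length for f in features):
        raise SizingError("length must be >= 10x the summed unit lengths")
    if total_planted >= length:
        raise SizingError("planted copies exceed the requested length")
    rng = np.random.default_rng(seed)
    assembly = list(random_dna(rng, length, gc))

    # place assembly copies at non-overlapping random positions
    placed: list[tuple[int, int]] = []
    planted: list[PlantedFeature] = []
    for spec in features:
        unit = random_dna(rng, spec.unit_length, gc)
        coords = []
        for c in range(spec.copies_in_assembly):
            for _ in range(1000):
                start = int(rng.integers(0, length - spec.unit_length + 1))
                iv = (start, start + spec.unit_length)
                if all(iv[1] <= s or iv[0] >= e for s, e in placed):
                    break
            else:
                raise SizingError("could not place features without overlap")
            placed.append(iv)
            copy = unit if c == 0 else _mutate(rng, unit, 1 - spec.identity)
            assembly[iv[0] : iv[1]] = copy
            coords.append(iv)
        planted.append(
            PlantedFeature(
                spec.kind,
                spec.unit_length,
                spec.copies_in_truth,
                spec.copies_in_assembly,
                sorted(coords),
            )
        )
        planted[-1]._unit = unit  # retained for truth construction
        planted[-1]._identity = spec.identity

    # truth = assembly with the collapsed extra copies inserted at random
    # background positions (never inside a planted interval)
    assembly_str = "".join(assembly)
    insertions: list[tuple[int, int]] = []  # (position in assembly, feature idx)
    for fi, f in enumerate(planted):
        extra = f.copies_in_truth - f.copies_in_assembly
        for _ in range(extra):
            for _ in range(1000):
                pos = int(rng.integers(0, length + 1))
                if all(pos <= s or pos >= e for s, e in placed):
                    break
            else:
                raise SizingError("could not find insertion points in background")
            insertions.append((pos, fi))
    insertions.sort()
    truth_parts = []
    cursor = 0
    offset = 0
    for pos, fi in insertions:
        truth_parts.append(assembly_str[cursor:pos])
        f = planted[fi]
        copy = _mutate(rng, f._unit, 1 - f._identity)
        start = pos + offset
        f.truth_coords.append((start, start + f.unit_length))
        truth_parts.append(copy)
        offset += f.unit_length
        cursor = pos
    truth_parts.append(assembly_str[cursor:])
    truth_str = "".join(truth_parts)

    gt = GenomeTruth({name: assembly_str}, {name: truth_str}, planted, seed)
    expected = length + sum(
        (f.copies_in_truth - f.copies_in_assembly) * f.unit_length for f in planted
    )
    assert gt.truth_length == expected
    return gt


# ---------------------------------------------------------------------------
# Uniform-depth single-end reads
# ---------------------------------------------------------------------------


def simulate_reads(
    truth: GenomeTruth | dict[str, str],
    depth: float,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Single-end error-optional reads drawn uniformly from the true genome.

    Read count is round(depth * truth_length / read_length); positions are
    uniform over each sequence (weighted by length), strands equiprobable,
    errors are substitutions only.  Returns (read_id, sequence) pairs.
    """
    seqs = truth.truth if isinstance(truth, GenomeTruth) else dict(truth)
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    for name, s in seqs.items():
        if read_length >= len(s):
            raise ValueError(f"read_length exceeds sequence {name!r}")
    rng = np.random.default_rng(seed)
    names = list(seqs)
    lengths = np.array([len(seqs[n]) for n in names], dtype=float)
    total = int(lengths.sum())
    n_reads = round(depth * total / read_length)
    which = rng.choice(len(names), size=n_reads, p=lengths / lengths.sum())
    reads = []
    for i in range(n_reads):
        s = seqs[names[which[i]]]
        start = int(rng.integers(0, len(s) - read_length + 1))
        seq = s[start : start + read_length]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        seq = _mutate(rng, seq, error_rate)
        reads.append((f"read_{i}", seq))
    return reads


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# Codon pairs diverged to a target Ks
# ---------------------------------------------------------------------------

MAX_TARGET_KS = 3.0  # implied p approaches the 3/4 JC saturation bound above this


def _synonymous_options(codon: str) -> list[str]:
    aa = CODON_AA[codon]
    out = []
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_AA[alt] == aa:
                out.append(alt)
    return out


def simulate_codon_pairs(
    n_pairs: int,
    target_ks: float,
    n_codons: int = 300,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Coding-sequence pairs whose NG86+JC Ks is close to target_ks.

    For each pair an ancestor of random sense codons is drawn; synonymous
    single-base substitutions are placed at distinct codons until the
    realised proportion of synonymous differences matches the target under
    the JC correction.  Returns (pairs, manifest); the manifest records the
    synonymous site total and substitution count actually planted.
    """
    if target_ks < 0:
        raise ValueError("target_ks must be >= 0")
    if target_ks > MAX_TARGET_KS:
        raise ValueError(
            f"target_ks {target_ks} beyond correction saturation "
            f"(max {MAX_TARGET_KS})"
        )
    if n_codons < 30:
        raise ValueError("n_codons must be >= 30")
    rng = np.random.default_rng(seed)
    p_target = 0.75 * -math.expm1(-4.0 * target_ks / 3.0)
    pairs = []
    rows = []
    for k in range(n_pairs):
        codons = list(rng.choice(SENSE_CODONS, size=n_codons))
        S = sum(syn_sites(c) for c in codons)
        n_subs = int(round(p_target * S))
        editable = [i for i, c in enumerate(codons) if _synonymous_options(c)]
        if n_subs > len(editable):
            raise ValueError("target_ks too high for the available synonymous sites")
        hit = rng.choice(len(editable), size=n_subs, replace=False)
        derived = list(codons)
        for idx in hit:
            i = editable[idx]
            opts = _synonymous_options(codons[i])
            derived[i] = opts[rng.integers(len(opts))]
        seq_a = "".join(codons)
        seq_b = "".join(derived)
        pairs.append((seq_a, seq_b))
        realized_ks = jukes_cantor(n_subs / S) if S else 0.0
        rows.append(
            {
                "pair": k,
                "n_codons": n_codons,
                "syn_sites_ancestor": S,
                "n_substitutions": n_subs,
                "target_ks": target_ks,
                "planted_ks": realized_ks,
            }
        )
    return pairs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synteny anchor sets with planted ploidy structure
# ---------------------------------------------------------------------------


@dataclass
class SyntenyEvent:
    """One planted homology event on the reference."""

    multiplicity: int
    fraction_of_genome: float
    median_ks: float
    ks_sd: float = 0.03


def plant_synteny(
    ref_length: int,
    events: list[SyntenyEvent],
    seed: int = 0,
    anchors_per_10kb: float = 5.0,
    min_block: int = 5,
    gene_length: int = 1000,
    ref_name: str = "ref1",
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Anchor table with planted multi-fold synteny and its true depth profile.

    Each event claims a disjoint slice of the reference spanning
    fraction_of_genome; `multiplicity` query chromosomes each carry a
    collinear anchor run whose footprint is exactly that slice, so the true
    synteny depth profile has fraction_of_genome of the genome at depth
    `multiplicity`.  Per-anchor Ks is drawn Normal(median_ks, ks_sd),
    truncated at zero.
    """
    if any(e.multiplicity < 1 for e in events):
        raise ValueError("multiplicities must be >= 1")
    if sum(e.fraction_of_genome for e in events) > 1 + 1e-9:
        raise ValueError("fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict[int, float] = {}
    cursor = 0
    for ei, ev in enumerate(events):
        span = int(round(ev.fraction_of_genome * ref_length))
        region = (cursor, cursor + span)
        cursor += span
        n_anchors = max(min_block, int(round(anchors_per_10kb * span / 10_000)))
        starts = np.linspace(region[0], region[1] - gene_length, n_anchors).astype(int)
        starts[0] = region[0]
        for copy in range(ev.multiplicity):
            chr_b = f"q{ei}_{copy}"
            for ai, s in enumerate(starts):
                e = int(s) + gene_length
                if ai == len(starts) - 1:
                    e = region[1]  # last anchor closes the footprint exactly
                ks_val = max(0.0, float(rng.normal(ev.median_ks, ev.ks_sd)))
                rows.append(
                    {
                        "gene_a": f"ref_e{ei}_g{ai}",
                        "chr_a": ref_name,
                        "start_a": int(s),
                        "end_a": e,
                        "gene_b": f"{chr_b}_g{ai}",
                        "chr_b": chr_b,
                        "start_b": int(s) - region[0],
                        "end_b": e - region[0],
                        "score": 100.0,
                        "ks": ks_val,
                    }
                )
        truth[ev.multiplicity] = truth.get(ev.multiplicity, 0.0) + span / ref_length
    truth[0] = 1.0 - sum(truth.values())
    anchors = pd.DataFrame(rows)
    return anchors, truth


# ---------------------------------------------------------------------------
# Modal-distance observations from a known tree
# ---------------------------------------------------------------------------


def simulate_modal_distances(
    tree: chron.EventTree,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[chron.ModalObservation]:
    """Observations implied by a tree with known branch lengths, plus noise.

    Emits one ortholog observation per unordered tip pair (path sum through
    the MRCA), one "old ortholog" observation per tip pair routed through
    the root when the MRCA is not already the root, and one paralog
    observation per (tip, ancestral duplication node or root) pair, each
    equal to its path sum plus Gaussian noise of sd noise_sd.
    """
    if any(n.length is None or n.length < 0 for n in tree.branch_nodes):
        raise ValueError("tree branch lengths must be set and >= 0")
    rng = np.random.default_rng(seed)
    obs: list[chron.ModalObservation] = []
    tips = tree.tips
    for i, tx in enumerate(tips):
        for ty in tips[i + 1 :]:
            mrca = tree.mrca(tx.name, ty.name)
            d = tree.ks_to_ancestor(tx.name, mrca.name) + tree.ks_to_ancestor(
                ty.name, mrca.name
            )
            obs.append(
                chron.ModalObservation(
                    "ortholog", tx.name, ty.name, max(0.0, d + rng.normal(0, noise_sd))
                )
            )
            if mrca is not tree.root:
                d_root = tree.ks_to_ancestor(
                    tx.name, tree.root.name
                ) + tree.ks_to_ancestor(ty.name, tree.root.name)
                obs.append(
                    chron.ModalObservation(
                        "ortholog",
                        tx.name,
                        ty.name,
                        max(0.0, d_root + rng.normal(0, noise_sd)),
                        through_root=True,
                    )
                )
    for tx in tips:
        ancestors = tree.ancestors(tx)
        for anc in ancestors:
            if anc.node_type in chron.DUPLICATION_TYPES:
                d = 2.0 * tree.ks_to_ancestor(tx.name, anc.name)
                obs.append(
                    chron.ModalObservation(
                        "paralog",
                        tx.name,
                        anc.name,
                        max(0.0, d + rng.normal(0, noise_sd)),
                    )
                )
    return obs
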