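"""Curation of control-region alignments into haplotype tables.

The raw material of an intraspecific mtDNA phylogeography study is a
pre-aligned set of control-region sequences, each tagged with a sampling
locality. Before any diversity or structure statistic is computed the
alignment is curated: hypervariable (homoplasic) columns are dropped,
length variation in tandem-repeat tracts is recoded so that a whole motif
counts as one mutational step, and identical sequences are pooled into
haplotypes with per-locality counts.

All site coordinates on the public surface are 1-based and inclusive,
matching the way positions are reported in the literature.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = set("ACGTN-")

__all__ = [
    "AlignmentRecord",
    "HaplotypeAlignment",
    "HaplotypeTable",
    "read_alignment",
    "write_alignment",
    "read_labels",
    "remove_sites",
    "collapse_repeat_motif",
    "collapse_haplotypes",
]


@dataclass(frozen=True)
class AlignmentRecord:
    sample_id: str
    population: str
    sequence: str


@dataclass
class HaplotypeAlignment:
    """A labelled, equal-length alignment over {A, C, G, T, -, N}.

    Invariants (checked on construction): all sequences share one length,
    sample ids are unique, and every record carries a population label.
    """

    records: list[AlignmentRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        L = len(self.records[0].sequence)
        seen: set[str] = set()
        for rec in self.records:
            if len(rec.sequence) != L:
                raise ValueError(
                    f"ragged alignment: record {rec.sample_id!r} has length "
                    f"{len(rec.sequence)}, expected {L}"
                )
            if rec.sample_id in seen:
                raise ValueError(f"duplicate sample id {rec.sample_id!r}")
            seen.add(rec.sample_id)
            if not rec.population:
                raise ValueError(f"record {rec.sample_id!r} has no population label")
            bad = set(rec.sequence.upper()) - ALPHABET
            if bad:
                raise ValueError(
                    f"record {rec.sample_id!r} contains invalid symbols {sorted(bad)}"
                )

    @property
    def L(self) -> int:
        """Alignment length in sites."""
        return len(self.records[0].sequence)

    @property
    def n(self) -> int:
        return len(self.records)

    def populations(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.population not in out:
                out.append(rec.population)
        return out

    def sequences(self) -> list[str]:
        return [rec.sequence for rec in self.records]


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample_id, population) into a mapping."""
    labels: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"label row {row!r} needs two columns")
            labels[row[0]] = row[1]
    return labels


def read_alignment(
    path: str | Path, labels: Mapping[str, str] | str | Path
) -> HaplotypeAlignment:
    """Read an aligned FASTA and attach population labels.

    ``labels`` maps sample id to population, or is a path to a TSV with
    those two columns. Records without a label are rejected.
    """
    if not isinstance(labels, Mapping):
        labels = read_labels(labels)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id not in labels:
            raise ValueError(f"no population label for sample {rec.id!r}")
        records.append(
            AlignmentRecord(rec.id, labels[rec.id], str(rec.seq).upper())
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return HaplotypeAlignment(records)


def write_alignment(aln: HaplotypeAlignment, fasta: str | Path, labels: str | Path | None = None) -> None:
    """Write the alignment back to FASTA (and optionally the label TSV)."""
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.sample_id, description="") for r in aln.records),
        str(fasta),
        "fasta",
    )
    if labels is not None:
        with open(labels, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            for r in aln.records:
                w.writerow([r.sample_id, r.population])


def remove_sites(aln: HaplotypeAlignment, positions: Iterable[int]) -> HaplotypeAlignment:
    """Drop the given 1-based columns from the alignment.

    Column order is otherwise preserved; duplicate positions are dropped
    once. Out-of-range positions raise ``ValueError``.
    """
    pos = sorted(set(int(p) for p in positions))
    L = aln.L
    for p in pos:
        if not 1 <= p <= L:
            raise ValueError(f"site {p} outside alignment of length {L}")
    drop = {p - 1 for p in pos}
    keep = [i for i in range(L) if i not in drop]
    records = [
        AlignmentRecord(r.sample_id, r.population, "".join(r.sequence[i] for i in keep))
        for r in aln.records
    ]
    return HaplotypeAlignment(records)


def _collapsed_tract(aln: HaplotypeAlignment, motif: str, start0: int) -> int | None:
    # Detect an already-collapsed tract: a run of columns holding either the
    # motif's first base or a gap in every sequence, with no full motif at
    # the start. Returns tract width or None.
    base = motif[0]
    width = 0
    L = aln.L
    for col in range(start0, L):
        states = {r.sequence[col] for r in aln.records}
        if states <= {base, "-"} and states != {"-"}:
            width += 1
        else:
            break
    if width == 0:
        return None
    for r in aln.records:
        if r.sequence[start0 : start0 + len(motif)] == motif:
            return None
    return width


def collapse_repeat_motif(
    aln: HaplotypeAlignment, motif: str, start: int
) -> HaplotypeAlignment:
    """Recode a tandem-repeat tract so each motif copy spans one column.

    Length variation in a microsatellite-like tract (e.g. a run of ``TA``
    repeats) would otherwise let a single replication slippage event count
    as ``len(motif)`` mutational steps. Within the tract, each complete
    motif copy is reduced to a single column carrying the motif's first
    base; missing copies become gap columns, so a difference of k copies
    becomes k single-column gap differences.

    The operation is idempotent: applying it to an already-collapsed tract
    returns the alignment unchanged.
    """
    motif = motif.upper()
    if len(motif) < 2:
        raise ValueError("motif must be at least 2 bases long")
    if not 1 <= start <= aln.L:
        raise ValueError(f"start {start} outside alignment of length {aln.L}")
    start0 = start - 1
    m = len(motif)

    if _collapsed_tract(aln, motif, start0) is not None:
        return HaplotypeAlignment(list(aln.records))

    # Per-sequence copy number: motif repeats read off after removing gaps,
    # so a shorter allele aligned with trailing gaps is handled.
    copies: list[int] = []
    tract_end0 = start0  # exclusive, in alignment columns
    for r in aln.records:
        k = 0
        col = start0
        buf = ""
        end = start0
        while col < aln.L:
            ch = r.sequence[col]
            if ch != "-":
                buf += ch
                if not motif.startswith(buf):
                    break
                if buf == motif:
                    k += 1
                    buf = ""
                    end = col + 1
            col += 1
        copies.append(k)
        tract_end0 = max(tract_end0, end)
    if all(k == 0 for k in copies):
        raise ValueError(
            f"motif {motif!r} not found at site {start} in any sequence"
        )

    kmax = max(copies)
    records = []
    for r, k in zip(aln.records, copies):
        head = r.sequence[:start0]
        tail = r.sequence[tract_end0:]
        tract = motif[0] * k + "-" * (kmax - k)
        records.append(AlignmentRecord(r.sample_id, r.population, head + tract + tail))
    return HaplotypeAlignment(records)


@dataclass
class HaplotypeTable:
    """Haplotype-by-population count matrix, the core data model.

    ``counts`` is a DataFrame indexed by haplotype id with one column per
    population. ``sequences`` maps haplotype id to its sequence when one
    is available (count-only tables, e.g. transcribed from a publication,
    carry no sequences). ``merge_log`` records which input labels were
    pooled into which haplotype, including ambiguity (N) resolutions.
    ``approximate`` flags haplotype rows whose counts are reconstructions
    rather than exact data.
    """

    counts: pd.DataFrame
    sequences: dict[str, str] = field(default_factory=dict)
    merge_log: list[tuple[tuple[str, ...], str]] = field(default_factory=list)
    approximate: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative haplotype counts")
        seqs = [s for s in self.sequences.values()]
        if len(set(seqs)) != len(seqs):
            raise ValueError("haplotype sequences are not pairwise distinct")

    @property
    def haplotypes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def populations(self) -> list[str]:
        return list(self.counts.columns)

    def population_counts(self, pop: str) -> pd.Series:
        if pop not in self.counts.columns:
            raise KeyError(f"unknown population {pop!r}")
        return self.counts[pop]

    def pooled(self, pops: Sequence[str], name: str | None = None) -> pd.Series:
        s = self.counts[list(pops)].sum(axis=1)
        s.name = name or "+".join(pops)
        return s

    def sample_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        df = self.counts.copy()
        df.insert(0, "sequence", [self.sequences.get(h, "") for h in df.index])
        df.to_csv(path, sep="\t", index_label="haplotype")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HaplotypeTable":
        df = pd.read_csv(path, sep="\t", index_col="haplotype")
        seqs = {}
        if "sequence" in df.columns:
            seqs = {h: s for h, s in df["sequence"].items() if isinstance(s, str) and s}
            df = df.drop(columns=["sequence"])
        return cls(counts=df.astype(int), sequences=seqs)


def _resolves(more: str, less: str) -> bool:
    # `more` strictly more resolved than `less`: equal everywhere except
    # positions where `less` has N and `more` has a base.
    strict = False
    for a, b in zip(more, less):
        if a == b:
            continue
        if b == "N" and a != "N":
            strict = True
        else:
            return False
    return strict


def collapse_haplotypes(
    aln: HaplotypeAlignment,
    hap_labels: Mapping[str, str] | None = None,
) -> HaplotypeTable:
    """Pool identical sequences into haplotypes with per-population counts.

    A sequence containing N is merged into another haplotype only when it
    is otherwise identical and the partner is strictly more resolved, and
    the merge partner is unique; this avoids inflating the haplotype count
    from partial sequences without guessing among ambiguous partners. Such
    merges are flagged in ``merge_log``.

    ``hap_labels`` optionally maps sample ids to externally assigned
    haplotype names; when distinct named haplotypes collapse into one, the
    pooled haplotype is named by joining the input names ("S+R") and the
    event is recorded in ``merge_log``.
    """
    groups: dict[str, list[AlignmentRecord]] = {}
    for rec in aln.records:
        groups.setdefault(rec.sequence, []).append(rec)

    merge_log: list[tuple[tuple[str, ...], str]] = []

    # Resolve N-bearing groups into a unique strictly-more-resolved partner.
    ambiguous = [s for s in groups if "N" in s]
    for seq in sorted(ambiguous):
        partners = [t for t in groups if t != seq and _resolves(t, seq)]
        if len(partners) == 1:
            target = partners[0]
            groups[target].extend(groups.pop(seq))
            merge_log.append(
                (tuple(r.sample_id for r in groups[target]), f"N-resolved into {target[:12]}..."),
            )

    # Deterministic haplotype order: by total count (desc), then sequence.
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))

    pops = aln.populations()
    names: list[str] = []
    seqs: dict[str, str] = {}
    rows = []
    for i, (seq, recs) in enumerate(ordered):
        if hap_labels is not None:
            labels = sorted({hap_labels[r.sample_id] for r in recs if r.sample_id in hap_labels})
            name = "+".join(labels) if labels else f"H{i + 1:02d}"
            if len(labels) > 1:
                merge_log.append((tuple(labels), name))
        else:
            name = f"H{i + 1:02d}"
        names.append(name)
        seqs[name] = seq
        row = {p: 0 for p in pops}
        for r in recs:
            row[r.population] += 1
        rows.append(row)

    counts = pd.DataFrame(rows, index=pd.Index(names, name="haplotype"), columns=pops)
    return HaplotypeTable(counts=counts, sequences=seqs, merge_log=merge_log)
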