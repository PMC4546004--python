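"""Sequence and haplotype I/O.

Reads aligned mtDNA fragments (FASTA) with a sample->population map, applies
fragment trimming rules (primer trims plus an optional homopolymer excision),
concatenates fragments per sample, collapses identical sequences into named
haplotypes, and builds population x haplotype count tables.

Haplotype naming follows the two-token convention used for concatenated
cytochrome-b + D-loop haplotypes: the coding-fragment haplotype is a letter
before the dash and the control-region haplotype a numeral after it
(e.g. ``D-9``). Count tables can be projected from the concatenated level
down to a single fragment by merging columns that share the relevant token.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .errors import DataError, MalformedSequenceError

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTN-")

CONCATENATED = "concatenated"
CYTB_ONLY = "cytb-only"
DLOOP_ONLY = "dloop-only"

#: which name token a single-fragment level keeps: 0 = before dash, 1 = after
_LEVEL_TOKEN = {CYTB_ONLY: 0, DLOOP_ONLY: 1}


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence for one sample at one fragment."""

    sample_id: str
    fragment_id: str
    bases: str
    population: str = ""
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        bases = self.bases.upper()
        object.__setattr__(self, "bases", bases)
        bad = set(bases) - VALID_BASES
        if bad:
            raise MalformedSequenceError(
                f"{self.sample_id}/{self.fragment_id}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class FragmentSpec:
    """Trimming rule for one amplified fragment.

    ``homopolymer_rule`` is ``(base, min_run, (start, stop))`` with the window
    a 0-based half-open interval on the already primer-trimmed sequence; the
    single maximal run of >= ``min_run`` copies of ``base`` inside the window
    is excised in full.
    """

    name: str
    five_prime_trim: int = 0
    three_prime_trim: int = 0
    homopolymer_rule: tuple[str, int, tuple[int, int]] | None = None
    target_length: int | None = None
    per_site_rate: float | None = None  # percent per million generations

    def __post_init__(self) -> None:
        if self.five_prime_trim < 0 or self.three_prime_trim < 0:
            raise MalformedSequenceError(f"{self.name}: negative trim")
        if self.target_length is not None and self.target_length <= 0:
            raise MalformedSequenceError(f"{self.name}: target_length must be > 0")
        if self.per_site_rate is not None and self.per_site_rate <= 0:
            raise MalformedSequenceError(f"{self.name}: per_site_rate must be > 0")


@dataclass(frozen=True)
class Haplotype:
    """A named haplotype: distinct sequence plus its fragment make-up."""

    name: str
    sequence: str
    fragment_composition: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.fragment_composition:
            total = sum(length for _, length in self.fragment_composition)
            if total != len(self.sequence):
                raise DataError(
                    f"haplotype {self.name}: fragment lengths sum to {total}, "
                    f"sequence is {len(self.sequence)} bp"
                )


def parse_haplotype_name(name: str) -> tuple[str, str]:
    """Split a concatenated haplotype name into (cytb token, dloop token)."""
    parts = name.split("-", 1)
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise DataError(f"haplotype name {name!r} does not parse into two tokens")
    return parts[0], parts[1]


class HaplotypeCountTable:
    """Populations x haplotypes occurrence matrix.

    Thin wrapper over a pandas DataFrame (integer counts, populations as rows)
    carrying the haplotype level and, optionally, the sequence length.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        level: str = CONCATENATED,
        sequence_length: int | None = None,
    ):
        if level not in (CONCATENATED, CYTB_ONLY, DLOOP_ONLY):
            raise DataError(f"unknown level {level!r}")
        counts = counts.fillna(0).astype(int)
        if (counts.to_numpy() < 0).any():
            raise DataError("negative haplotype counts")
        self.counts = counts
        self.level = level
        self.sequence_length = sequence_length

    @property
    def populations(self) -> list[str]:
        return list(self.counts.index)

    @property
    def haplotypes(self) -> list[str]:
        return list(self.counts.columns)

    def sample_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def haplotype_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def pooled(self, populations: Sequence[str] | None = None) -> np.ndarray:
        """Pool counts over the given populations (default: all); drop zeros."""
        sub = self.counts if populations is None else self.counts.loc[list(populations)]
        pooled = sub.sum(axis=0).to_numpy()
        return pooled[pooled > 0]

    def subset(self, populations: Sequence[str]) -> "HaplotypeCountTable":
        sub = self.counts.loc[list(populations)]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        return HaplotypeCountTable(sub, self.level, self.sequence_length)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeCountTable):
            return NotImplemented
        return self.level == other.level and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return (
            f"<HaplotypeCountTable {len(self.populations)} populations x "
            f"{len(self.haplotypes)} haplotypes, level={self.level}>"
        )

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# haplotype count table; level={self.level}")
            if self.sequence_length is not None:
                fh.write(f"; sequence_length={self.sequence_length}")
            fh.write("\n")
            self.counts.to_csv(fh, index_label="population")

    @classmethod
    def from_csv(cls, path: str | Path) -> "HaplotypeCountTable":
        path = Path(path)
        level, seq_len = CONCATENATED, None
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for part in first.lstrip("#").split(";"):
                    part = part.strip()
                    if part.startswith("level="):
                        level = part.split("=", 1)[1]
                    elif part.startswith("sequence_length="):
                        seq_len = int(part.split("=", 1)[1])
                df = pd.read_csv(fh, index_col="population")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, index_col="population")
        return cls(df, level=level, sequence_length=seq_len)


# ---------------------------------------------------------------------------
# trimming and concatenation


def _find_homopolymer_run(
    bases: str, base: str, min_run: int, window: tuple[int, int]
) -> tuple[int, int] | None:
    """Locate the maximal run of `base` (>= min_run) starting inside `window`.

    Returns (start, stop) half-open over the full sequence, extending the run
    past the window edge so it is excised in full; None if no qualifying run.
    """
    start, stop = window
    if start < 0 or stop > len(bases) or start >= stop:
        raise MalformedSequenceError(f"homopolymer window {window} outside sequence")
    best: tuple[int, int] | None = None
    i = start
    while i < stop:
        if bases[i] == base:
            j = i
            while j > 0 and bases[j - 1] == base:
                j -= 1
            k = i
            while k < len(bases) and bases[k] == base:
                k += 1
            if k - j >= min_run and (best is None or k - j > best[1] - best[0]):
                best = (j, k)
            i = k
        else:
            i += 1
    return best


def trim_fragment(record: SequenceRecord, spec: FragmentSpec) -> SequenceRecord:
    """Apply primer trims and the optional homopolymer excision to one read."""
    n = len(record.bases)
    if n < spec.five_prime_trim + spec.three_prime_trim:
        raise MalformedSequenceError(
            f"{record.sample_id}/{record.fragment_id}: length {n} shorter than "
            f"trims {spec.five_prime_trim}+{spec.three_prime_trim}"
        )
    end = n - spec.three_prime_trim
    bases = record.bases[spec.five_prime_trim : end]
    if spec.homopolymer_rule is not None:
        base, min_run, window = spec.homopolymer_rule
        run = _find_homopolymer_run(bases, base.upper(), min_run, window)
        if run is None:
            warnings.warn(
                f"{record.sample_id}/{spec.name}: no {base}-homopolymer of length "
                f">= {min_run} found in window {window}; sequence kept as is",
                stacklevel=2,
            )
        else:
            bases = bases[: run[0]] + bases[run[1] :]
    return replace(record, bases=bases, fragment_id=spec.name)


def concatenate_fragments(
    records: Iterable[SequenceRecord], order: Sequence[str]
) -> tuple[str, tuple[tuple[str, int], ...]]:
    """Concatenate one sample's fragments in the given order.

    Returns the concatenated bases and the (fragment, length) composition.
    """
    by_frag: dict[str, SequenceRecord] = {}
    for rec in records:
        if rec.fragment_id in by_frag:
            raise DataError(
                f"sample {rec.sample_id}: duplicate fragment {rec.fragment_id}"
            )
        by_frag[rec.fragment_id] = rec
    missing = [f for f in order if f not in by_frag]
    if missing:
        raise DataError(f"missing fragment(s) {missing}")
    parts = [by_frag[f].bases for f in order]
    composition = tuple((f, len(by_frag[f].bases)) for f in order)
    return "".join(parts), composition


def concatenate_samples(
    records: Iterable[SequenceRecord], order: Sequence[str]
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Concatenate fragments for every sample that has all of them.

    Samples missing a fragment are excluded with a logged reason (this is how
    a 180-sample single-fragment set shrinks to a 145-sample concatenated
    set). Returns (concatenated records, {excluded sample: reason}).
    """
    per_sample: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        per_sample.setdefault(rec.sample_id, []).append(rec)
    out: list[SequenceRecord] = []
    excluded: dict[str, str] = {}
    for sample_id, recs in per_sample.items():
        have = {r.fragment_id for r in recs}
        missing = [f for f in order if f not in have]
        if missing:
            reason = f"missing fragment(s) {','.join(missing)}"
            excluded[sample_id] = reason
            logger.info("excluding sample %s: %s", sample_id, reason)
            continue
        bases, _ = concatenate_fragments(recs, order)
        first = recs[0]
        out.append(
            SequenceRecord(
                sample_id=sample_id,
                fragment_id="+".join(order),
                bases=bases,
                population=first.population,
                latitude=first.latitude,
                longitude=first.longitude,
            )
        )
    return out, excluded


# ---------------------------------------------------------------------------
# haplotype collapsing


def _compatible(seq: str, reference: str) -> bool:
    """True if seq matches reference everywhere seq is unambiguous."""
    return all(a == b for a, b in zip(seq, reference) if a != "N")


def _letter_name(i: int) -> str:
    """0 -> A, 25 -> Z, 26 -> AA, ..."""
    name = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        name = chr(ord("A") + rem) + name
    return name


def _haplotype_names(
    sequences: list[str], composition: tuple[tuple[str, int], ...] | None
) -> list[str]:
    """Name haplotypes; two-fragment sets get the letter-numeral convention."""
    if composition is not None and len(composition) == 2:
        len_a = composition[0][1]
        letters: dict[str, str] = {}
        numbers: dict[str, str] = {}
        names = []
        for seq in sequences:
            a, b = seq[:len_a], seq[len_a:]
            if a not in letters:
                letters[a] = _letter_name(len(letters))
            if b not in numbers:
                numbers[b] = str(len(numbers) + 1)
            names.append(f"{letters[a]}-{numbers[b]}")
        return names
    return [f"H{i + 1}" for i in range(len(sequences))]


@dataclass
class CollapseResult:
    """Haplotype list, count table and any unresolvable records."""

    haplotypes: list[Haplotype]
    table: HaplotypeCountTable
    excluded: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        return iter((self.haplotypes, self.table))


def collapse_haplotypes(
    records: Sequence[SequenceRecord],
    composition: tuple[tuple[str, int], ...] | None = None,
    level: str = CONCATENATED,
) -> CollapseResult:
    """Collapse aligned sequences into haplotypes and tally counts.

    Fully unambiguous sequences (gaps count as a fifth state) define the
    haplotype classes, ordered by first observation. A record containing N is
    assigned only if compatible with exactly one existing class; otherwise it
    is excluded and logged as unresolvable.
    """
    if not records:
        raise DataError("no records to collapse")
    lengths = {len(r.bases) for r in records}
    if len(lengths) != 1:
        raise DataError(f"sequences of unequal length: {sorted(lengths)}")

    classes: list[str] = []  # unambiguous class sequences, first-observation order
    index: dict[str, int] = {}
    members: list[list[SequenceRecord]] = []
    ambiguous: list[SequenceRecord] = []
    for rec in records:
        if "N" in rec.bases:
            ambiguous.append(rec)
            continue
        if rec.bases not in index:
            index[rec.bases] = len(classes)
            classes.append(rec.bases)
            members.append([])
        members[index[rec.bases]].append(rec)

    excluded: dict[str, str] = {}
    for rec in ambiguous:
        hits = [i for i, cls in enumerate(classes) if _compatible(rec.bases, cls)]
        if len(hits) == 1:
            members[hits[0]].append(rec)
        else:
            reason = (
                "ambiguous sites compatible with "
                f"{len(hits)} haplotypes" if hits else "ambiguous sites match no haplotype"
            )
            excluded[rec.sample_id] = reason
            logger.warning("excluding %s: %s", rec.sample_id, reason)

    names = _haplotype_names(classes, composition)
    haplotypes = [
        Haplotype(name=n, sequence=s, fragment_composition=composition or ())
        for n, s in zip(names, classes)
    ]
    pops: list[str] = []
    for recs in members:
        for r in recs:
            if r.population not in pops:
                pops.append(r.population)
    counts = pd.DataFrame(0, index=pops, columns=names, dtype=int)
    for name, recs in zip(names, members):
        for r in recs:
            counts.loc[r.population, name] += 1
    seq_len = lengths.pop()
    table = HaplotypeCountTable(counts, level=level, sequence_length=seq_len)
    return CollapseResult(haplotypes, table, excluded)


def project_counts(table: HaplotypeCountTable, level: str) -> HaplotypeCountTable:
    """Project a concatenated-level table to a single-fragment level.

    Columns sharing the relevant name token merge (B-2 and D-2 both become
    D-loop haplotype "2"); counts sum, so the table total is conserved.
    """
    if level == table.level:
        return table
    if table.level != CONCATENATED:
        raise DataError(f"cannot project a {table.level} table to {level}")
    if level not in _LEVEL_TOKEN:
        raise DataError(f"unknown level {level!r}")
    token_idx = _LEVEL_TOKEN[level]
    merged: dict[str, list[str]] = {}
    for col in table.haplotypes:
        token = parse_haplotype_name(col)[token_idx]
        merged.setdefault(token, []).append(col)
    out = pd.DataFrame(index=table.populations)
    for token, cols in merged.items():
        out[token] = table.counts[cols].sum(axis=1)
    return HaplotypeCountTable(out, level=level)


# ---------------------------------------------------------------------------
# file formats


def read_fasta(
    path: str | Path,
    fragment_id: str | None = None,
    population_map: Mapping[str, Mapping[str, object]] | None = None,
) -> list[SequenceRecord]:
    """Read FASTA. Headers are ``sampleID`` or ``sampleID|fragment``."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" in rec.id:
            sample_id, frag = rec.id.split("|", 1)
        else:
            sample_id, frag = rec.id, fragment_id or "fragment"
        meta = dict(population_map.get(sample_id, {})) if population_map else {}
        records.append(
            SequenceRecord(
                sample_id=sample_id,
                fragment_id=frag,
                bases=str(rec.seq).upper(),
                population=str(meta.get("population", "")),
                latitude=meta.get("latitude"),
                longitude=meta.get("longitude"),
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        BioSeqRecord(Seq(r.bases), id=f"{r.sample_id}|{r.fragment_id}", description="")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_population_map(path: str | Path) -> dict[str, dict[str, object]]:
    """Tab-separated: sample_id, population[, latitude, longitude]."""
    out: dict[str, dict[str, object]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"population map line {line!r}: need >= 2 columns")
            entry: dict[str, object] = {"population": parts[1]}
            if len(parts) >= 4 and parts[2] and parts[3]:
                entry["latitude"] = float(parts[2])
                entry["longitude"] = float(parts[3])
            out[parts[0]] = entry
    return out


def write_population_map(
    records: Iterable[SequenceRecord], path: str | Path
) -> None:
    seen = set()
    with open(path, "w") as fh:
        for r in records:
            if r.sample_id in seen:
                continue
            seen.add(r.sample_id)
            if r.latitude is not None and r.longitude is not None:
                fh.write(f"{r.sample_id}\t{r.population}\t{r.latitude}\t{r.longitude}\n")
            else:
                fh.write(f"{r.sample_id}\t{r.population}\n")
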