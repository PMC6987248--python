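"""Quality control for mined barcode sequences (matK/trnK and rbcL).

An offline, auditable re-implementation of the GenBank-mining filter
cascade: a similarity screen against a reference panel (a reproducible
stand-in for a megablast check of each record against its claimed
identity), best-accession selection per species, ambiguity filtering,
removal of species with conflicting duplicate sequences, a reading-frame /
amino-acid shift screen for the protein-coding spans, and dual-checklist
validation of taxon names.  Every verdict is recorded with the rule that
fired, and kept + dropped always equals the input count.

Local alignments are computed with edlib; translation uses Biopython's
genetic codes (the plastid/bacterial code, table 11, by default).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "TaxonRecord",
    "Checklist",
    "QCReport",
    "similarity_screen",
    "select_best_accession",
    "filter_ambiguous",
    "drop_conflicting_duplicates",
    "screen_frameshift",
    "validate_names",
    "run_qc",
    "read_fasta",
    "write_fasta",
    "normalize_binomial",
]

MARKERS = ("matK_trnK", "rbcL")
_ACGT = set("ACGT")

# Karlin-Altschul-style constants for a +1/-2 match/mismatch scheme; used
# only to turn alignment scores into an E-value-like quantity for the
# offline similarity screen.
_KA_LAMBDA = 1.33
_KA_K = 0.62


@dataclass(frozen=True)
class TaxonRecord:
    """One sequence record: species binomial, marker, accession, sequence."""

    species_name: str
    marker: str
    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if self.marker not in MARKERS:
            raise ValueError(f"{self.accession}: unknown marker {self.marker!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def ambiguous_count(self) -> int:
        return sum(1 for b in self.sequence if b not in _ACGT)

    @property
    def ambiguous_fraction(self) -> float:
        return self.ambiguous_count / self.length


def normalize_binomial(name: str) -> str:
    parts = re.split(r"\s+", name.strip())
    if not parts or not parts[0]:
        return ""
    genus = parts[0].capitalize()
    rest = [p.lower() for p in parts[1:]]
    return " ".join([genus] + rest)


@dataclass
class Checklist:
    """A set of accepted binomials (an offline name-resolution authority)."""

    name: str
    valid_names: frozenset[str]

    @classmethod
    def from_names(cls, name: str, names: Iterable[str]) -> "Checklist":
        return cls(name=name, valid_names=frozenset(normalize_binomial(n) for n in names))

    @classmethod
    def from_file(cls, name: str, path) -> "Checklist":
        names = []
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    names.append(line)
        return cls.from_names(name, names)

    def __contains__(self, name: str) -> bool:
        return normalize_binomial(name) in self.valid_names


@dataclass
class QCReport:
    """Audit trail: one (verdict, rule, detail) entry per input record."""

    entries: list[dict] = field(default_factory=list)

    def add(self, record: TaxonRecord, verdict: str, rule: str = "", detail: str = "") -> None:
        self.entries.append(
            {
                "accession": record.accession,
                "species": record.species_name,
                "marker": record.marker,
                "verdict": verdict,
                "rule": rule,
                "detail": detail,
            }
        )

    @property
    def kept(self) -> int:
        return sum(1 for e in self.entries if e["verdict"] == "kept")

    @property
    def dropped(self) -> int:
        return sum(1 for e in self.entries if e["verdict"] == "dropped")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["accession", "species", "marker", "verdict", "rule", "detail"]
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alignment helpers


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _align_score(query: str, target: str) -> int:
    """Alignment score under +1 match / -2 mismatch-or-gap, infix mode."""
    shorter, longer = (query, target) if len(query) <= len(target) else (target, query)
    dist = edlib.align(shorter, longer, mode="HW")["editDistance"]
    return len(shorter) - 3 * dist  # each error forfeits a match and costs 2


def _evalue(score: int, m: int, n: int) -> float:
    if score <= 0:
        return math.inf
    return _KA_K * m * n * math.exp(-_KA_LAMBDA * score)


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: 1 − edit distance / longer length."""
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, mode="NW")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


# ---------------------------------------------------------------------------
# the filter rules


def similarity_screen(
    record: TaxonRecord,
    references: Sequence[TaxonRecord],
    taxonomy: Mapping[str, str],
    min_evalue: float = 0.0005,
    word_size: int = 8,
    max_hits: int = 250,
) -> tuple[str, str, str]:
    """Keep a record iff its best reference hit is from its own family.

    A reproducible surrogate for blasting each record against the source
    database and discarding sequences anomalous against their claimed
    identity: candidate references must share an exact ``word_size``-mer
    with the record (capped at ``max_hits`` candidates), hits worse than
    the ``min_evalue`` threshold are ignored, and the verdict compares the
    best hit's family (via ``taxonomy``: species → family) with the
    record's.  Returns (verdict, rule, detail).
    """
    if not references:
        raise ValueError("empty reference panel")
    if record.length < word_size:
        return "dropped", "too_short", f"length {record.length} < word size {word_size}"
    words = _kmers(record.sequence, word_size)
    candidates = []
    for ref in references:
        if ref.accession == record.accession:
            continue
        if words & _kmers(ref.sequence, word_size):
            candidates.append(ref)
        if len(candidates) >= max_hits:
            break
    best = None
    best_score = -1
    for ref in candidates:
        score = _align_score(record.sequence, ref.sequence)
        if _evalue(score, record.length, ref.length) > min_evalue:
            continue
        if score > best_score or (
            score == best_score and best is not None and ref.accession < best.accession
        ):
            best, best_score = ref, score
    if best is None:
        return "dropped", "no_hit", "no reference hit passed the E-value threshold"
    rec_family = taxonomy.get(normalize_binomial(record.species_name))
    hit_family = taxonomy.get(normalize_binomial(best.species_name))
    if rec_family is None:
        return "dropped", "unknown_family", f"{record.species_name} not in taxonomy"
    if rec_family != hit_family:
        return (
            "dropped",
            "cross_family_hit",
            f"best hit {best.accession} ({best.species_name}) is in family "
            f"{hit_family}, record claims {rec_family}",
        )
    return "kept", "similarity_screen", f"best hit {best.accession} ({best.species_name})"


def select_best_accession(records: Sequence[TaxonRecord]) -> TaxonRecord:
    """The single representative accession for one species+marker.

    Lexicographic preference: fewest ambiguity symbols per base (the only
    quality signal available from sequence text), then greatest length,
    then highest mean pairwise identity to the species' other accessions;
    deterministic final tie-break on the accession string.
    """
    if not records:
        raise ValueError("no records to choose from")
    keys = {(r.species_name, r.marker) for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span multiple species/markers: {sorted(keys)}")
    if len(records) == 1:
        return records[0]

    def mean_identity(rec: TaxonRecord) -> float:
        others = [r for r in records if r is not rec]
        return sum(pairwise_identity(rec.sequence, r.sequence) for r in others) / len(others)

    return min(
        records,
        key=lambda r: (r.ambiguous_fraction, -r.length, -mean_identity(r), r.accession),
    )


def filter_ambiguous(record: TaxonRecord, max_ambiguous_frac: float = 0.01) -> tuple[str, str, str]:
    """Drop sequences with multiple ambiguity symbols.

    Dropped iff the non-ACGT fraction exceeds ``max_ambiguous_frac``, or —
    reading "multiple" literally for short sequences where the fractional
    threshold would allow it — the absolute count is ≥ 2 while
    length × frac < 2.
    """
    count = record.ambiguous_count
    frac = record.ambiguous_fraction
    if frac > max_ambiguous_frac:
        return "dropped", "ambiguous_fraction", f"{count}/{record.length} = {frac:.4f} > {max_ambiguous_frac}"
    if count >= 2 and record.length * max_ambiguous_frac < 2:
        return "dropped", "multiple_ambiguities", f"{count} ambiguous bases"
    return "kept", "filter_ambiguous", f"{count} ambiguous bases"


def drop_conflicting_duplicates(
    records: Sequence[TaxonRecord], max_divergence: float = 0.05
) -> tuple[list[TaxonRecord], QCReport]:
    """Resolve same-name duplicates; drop species with conflicting sequences.

    Within each species+marker group: if any pair of accessions diverges by
    more than ``max_divergence`` p-distance the whole species is removed
    (same name, different sequences — identity unresolvable); otherwise the
    group is de-duplicated to its best representative.
    """
    report = QCReport()
    groups: dict[tuple[str, str], list[TaxonRecord]] = {}
    for rec in records:
        groups.setdefault((rec.species_name, rec.marker), []).append(rec)
    kept: list[TaxonRecord] = []
    for (species, marker), group in groups.items():
        if len(group) == 1:
            kept.append(group[0])
            report.add(group[0], "kept", "deduplicate", "single accession")
            continue
        worst = 0.0
        pair = None
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                d = 1.0 - pairwise_identity(group[i].sequence, group[j].sequence)
                if d > worst:
                    worst, pair = d, (group[i].accession, group[j].accession)
        if worst > max_divergence:
            for rec in group:
                report.add(
                    rec,
                    "dropped",
                    "conflicting_duplicates",
                    f"{pair[0]} vs {pair[1]} diverge {worst:.3f} > {max_divergence}",
                )
            continue
        best = select_best_accession(group)
        kept.append(best)
        for rec in group:
            if rec is best:
                report.add(rec, "kept", "deduplicate", f"representative of {len(group)}")
            else:
                report.add(rec, "dropped", "not_best_accession", f"{best.accession} preferred")
    return kept, report


def _find_orf(seq: str, table: CodonTable.CodonTable) -> tuple[int, int]:
    """Longest stop-free in-frame window across the three forward frames."""
    best = (0, 0)
    for frame in range(3):
        start = frame
        i = frame
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if codon in table.stop_codons:
                if i - start > best[1] - best[0]:
                    best = (start, i)
                start = i + 3
            i += 3
        if i - start > best[1] - best[0]:
            best = (start, i)
    return best


def screen_frameshift(
    record: TaxonRecord,
    frame: int = 0,
    genetic_code: int = 11,
    reference_protein: str | None = None,
    min_identity: float = 0.7,
) -> tuple[str, str, str]:
    """Reading-frame screen for protein-coding spans.

    For rbcL the coding span starts at ``frame``; for matK (a coding ORF
    inside the trnK intron) the span is located by a stop-free ORF scan.
    Dropped on an internal stop codon, a coding span shorter than half the
    sequence (frame disruption), or — when a same-family reference protein
    is supplied — translated identity below ``min_identity`` (the "sudden
    amino-acid shift" surrogate).
    """
    try:
        table = CodonTable.unambiguous_dna_by_id[genetic_code]
    except KeyError as exc:
        raise ValueError(f"unknown genetic code id {genetic_code}") from exc
    seq = re.sub(r"[^ACGT]", "N", record.sequence)
    if record.marker == "matK_trnK":
        start, end = _find_orf(seq, table)
        if end - start < len(seq) // 2:
            return "dropped", "frame_shift", f"longest ORF {end - start} nt of {len(seq)}"
    else:
        start = frame
        end = start + ((len(seq) - start) // 3) * 3
    span = seq[start:end]
    if len(span) % 3 != 0:
        return "dropped", "frame_shift", "coding span not a codon multiple"
    protein = str(Seq(span).translate(table=genetic_code))
    if "*" in protein[:-1]:
        return "dropped", "internal_stop", f"stop codon at aa {protein.index('*') + 1}"
    if reference_protein is not None:
        ident = pairwise_identity(protein.rstrip("*"), reference_protein.rstrip("*"))
        if ident < min_identity:
            return "dropped", "aa_shift", f"protein identity {ident:.3f} < {min_identity}"
    return "kept", "screen_frameshift", f"coding span {len(span)} nt"


def validate_names(
    names: Sequence[str], checklist_a: Checklist, checklist_b: Checklist
) -> list[str]:
    """Names accepted by BOTH checklists (order-preserving, normalized)."""
    for cl in (checklist_a, checklist_b):
        if not cl.valid_names:
            raise ValueError(f"checklist {cl.name!r} is empty")
    out = []
    for name in names:
        norm = normalize_binomial(name)
        if norm in checklist_a.valid_names and norm in checklist_b.valid_names:
            out.append(norm)
    return out


# ---------------------------------------------------------------------------
# the full cascade


def run_qc(
    records: Sequence[TaxonRecord],
    references: Sequence[TaxonRecord],
    taxonomy: Mapping[str, str],
    checklist_a: Checklist,
    checklist_b: Checklist,
    min_evalue: float = 0.0005,
    word_size: int = 8,
    max_hits: int = 250,
    max_ambiguous_frac: float = 0.01,
    max_divergence: float = 0.05,
    reference_proteins: Mapping[str, str] | None = None,
    min_protein_identity: float = 0.7,
) -> tuple[list[TaxonRecord], QCReport]:
    """The full filter chain; returns (kept records, per-record report).

    Order: similarity screen → ambiguity filter → frame/AA screen →
    duplicate resolution (best accession per species, conflicting species
    dropped) → dual-checklist name validation.  Verdicts are independent
    of input order (ties break on accession strings), the chain is
    idempotent, and kept + dropped equals the input count.
    """
    report = QCReport()
    stage1: list[TaxonRecord] = []
    for rec in records:
        verdict, rule, detail = similarity_screen(
            rec, references, taxonomy, min_evalue, word_size, max_hits
        )
        if verdict == "dropped":
            report.add(rec, "dropped", rule, detail)
            continue
        verdict, rule, detail = filter_ambiguous(rec, max_ambiguous_frac)
        if verdict == "dropped":
            report.add(rec, "dropped", rule, detail)
            continue
        ref_prot = None
        if reference_proteins is not None:
            family = taxonomy.get(normalize_binomial(rec.species_name))
            ref_prot = reference_proteins.get(family) if family else None
        verdict, rule, detail = screen_frameshift(
            rec, reference_protein=ref_prot, min_identity=min_protein_identity
        )
        if verdict == "dropped":
            report.add(rec, "dropped", rule, detail)
            continue
        stage1.append(rec)

    stage2, dup_report = drop_conflicting_duplicates(stage1, max_divergence)
    report.entries.extend(dup_report.entries)

    valid = set(
        validate_names([r.species_name for r in stage2], checklist_a, checklist_b)
    )
    kept = []
    for rec in stage2:
        if normalize_binomial(rec.species_name) in valid:
            kept.append(rec)
            # upgrade the dedup entry is unnecessary: entry already "kept"
        else:
            for entry in report.entries:
                if entry["accession"] == rec.accession and entry["verdict"] == "kept":
                    entry["verdict"] = "dropped"
                    entry["rule"] = "invalid_name"
                    entry["detail"] = "name not accepted by both checklists"
    assert report.kept + report.dropped == len(records)
    return kept, report


# ---------------------------------------------------------------------------
# FASTA I/O (headers: "Accession|Species name|marker")


def read_fasta(path) -> list[TaxonRecord]:
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        parts = header.split("|")
        if len(parts) != 3:
            raise ValueError(f"malformed header {header!r}: expected Accession|Species|marker")
        accession, species, marker = (p.strip() for p in parts)
        records.append(
            TaxonRecord(
                species_name=species.replace("_", " "),
                marker=marker,
                accession=accession,
                sequence=str(rec.seq),
            )
        )
    return records


def write_fasta(records: Sequence[TaxonRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            species = rec.species_name.replace(" ", "_")
            fh.write(f">{rec.accession}|{species}|{rec.marker}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")
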