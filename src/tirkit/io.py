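"""File formats, configuration and run manifests.

Coordinates are 0-based half-open everywhere inside the package; GFF3 and the
human-readable reports use 1-based inclusive coordinates, BED stays 0-based
half-open.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import ElementCopy
from .detect import CandidateCopy, SeedHit
from .motif import MotifProfile


# ---------------------------------------------------------------------------
# coordinate conventions
# ---------------------------------------------------------------------------

def span_to_gff(span: tuple[int, int]) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return span[0] + 1, span[1]


def gff_to_span(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1


def interval_1based_length(start1: int, end1: int) -> int:
    """Length of a 1-based inclusive interval, as printed in reports."""
    if end1 < start1:
        raise ValueError("end before start")
    return end1 - start1 + 1


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """A report percentage, rounded the way the summaries print it."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round(100.0 * numerator / denominator, ndigits)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records as an ordered id -> uppercase-sequence mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA identifier {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def hits_to_frame(hits: Sequence[SeedHit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "contig": h.contig, "start": h.start, "end": h.end, "strand": h.strand,
        "query_id": h.query_id, "query_start": h.query_span[0],
        "query_end": h.query_span[1], "identity": round(h.identity, 4),
        "score": h.score,
    } for h in hits])


def candidates_to_frame(cands: Sequence[CandidateCopy]) -> pd.DataFrame:
    return pd.DataFrame([{
        "contig": c.contig, "start": c.span[0], "end": c.span[1],
        "strand": c.strand, "n_hits": len(c.member_hits),
        "queries": ",".join(sorted({h.query_id for h in c.member_hits})),
    } for c in cands])


def copies_to_frame(copies: Sequence[ElementCopy]) -> pd.DataFrame:
    """Per-copy annotation table (1-based inclusive coordinates)."""
    rows = []
    for c in copies:
        s1, e1 = span_to_gff(c.span)
        rows.append({
            "copy_id": c.copy_id, "contig": c.contig, "start": s1, "end": e1,
            "strand": c.strand, "group": c.group,
            "length": c.span[1] - c.span[0],
            "tir_a_len": c.tir_pair.lengths[0] if c.tir_pair else (
                c.single_tir_span[1] - c.single_tir_span[0] if c.single_tir_span else 0),
            "tir_b_len": c.tir_pair.lengths[1] if c.tir_pair else 0,
            "tir_identity": round(c.tir_pair.percent_identity, 4) if c.tir_pair else "",
            "tsd": c.tsd.left_seq if c.tsd else "",
            "tsd_len": c.tsd.length if c.tsd else 0,
            "tsd_mismatches": c.tsd.mismatches if c.tsd else "",
            "tsd_status": c.tsd_status,
            "tpase_coverage": round(c.tpase_coverage, 3),
            "n_nested": len(c.nested_insertions),
            "n_flanking": len(c.flanking_insertions),
        })
    return pd.DataFrame(rows)


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3 / BED
# ---------------------------------------------------------------------------

_SOURCE = "tirkit"


def write_gff3(copies: Sequence[ElementCopy], path: str | Path,
               contig_lengths: Mapping[str, int] | None = None) -> None:
    """Hierarchical GFF3: element features with TIR / TPase_segment / TSD /
    nested_TE / AT_rich / tandem_repeat children."""
    lines = ["##gff-version 3"]
    for c in sorted(copies, key=lambda x: (x.contig, x.span)):
        if contig_lengths is not None:
            n = contig_lengths[c.contig]
            if c.span[0] < 0 or c.span[1] > n:
                raise ValueError(f"{c.copy_id}: span outside contig bounds")
        eid = c.copy_id
        s1, e1 = span_to_gff(c.span)

        def row(ftype: str, span: tuple[int, int], attrs: str) -> str:
            a, b = span_to_gff(span)
            return "\t".join([c.contig, _SOURCE, ftype, str(a), str(b), ".",
                              c.strand, ".", attrs])

        lines.append(row("element", c.span, f"ID={eid};structural_group={c.group}"))
        if c.tir_pair is not None:
            lines.append(row("TIR", c.tir_pair.tir5_span, f"Parent={eid};arm=5p"))
            lines.append(row("TIR", c.tir_pair.tir3_span, f"Parent={eid};arm=3p"))
        elif c.single_tir_span is not None:
            lines.append(row("TIR", c.single_tir_span, f"Parent={eid};arm=single"))
        for sp in c.tpase_spans:
            lines.append(row("TPase_segment", sp, f"Parent={eid}"))
        if c.tsd is not None:
            s, e = c.span
            k = c.tsd.length
            lines.append(row("TSD", (s - k, s), f"Parent={eid};side=left;seq={c.tsd.left_seq}"))
            lines.append(row("TSD", (e, e + k), f"Parent={eid};side=right;seq={c.tsd.right_seq}"))
        for ann in c.nested_insertions + c.flanking_insertions:
            lines.append(row("nested_TE", ann.span,
                             f"Parent={eid};Name={ann.te_label};placement={ann.placement};"
                             f"identity={ann.identity:.3f}"))
        for sp in c.at_rich_segments:
            lines.append(row("AT_rich", sp, f"Parent={eid}"))
        for sp, period, copies_n in c.tandem_repeat_regions:
            lines.append(row("tandem_repeat", sp,
                             f"Parent={eid};period={period};copies={copies_n}"))
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed(intervals: Iterable[tuple[str, int, int, str, float, str]],
              path: str | Path) -> None:
    """BED6 rows (contig, start, end, name, score, strand), 0-based half-open."""
    rows = sorted(intervals, key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for contig, s, e, name, score, strand in rows:
            fh.write(f"{contig}\t{s}\t{e}\t{name}\t{score:g}\t{strand}\n")


# ---------------------------------------------------------------------------
# motif profile export
# ---------------------------------------------------------------------------

def profile_to_frame(profile: MotifProfile) -> pd.DataFrame:
    df = pd.DataFrame(profile.counts, columns=list("ACGT"))
    df.insert(0, "position", np.arange(1, profile.length + 1))
    df["consensus"] = list(profile.consensus)
    df["information_bits"] = np.round(profile.information_content, 4)
    return df


def profile_to_minimal_meme(profile: MotifProfile, name: str = "TSM") -> str:
    freqs = profile.frequencies()
    lines = [
        "MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", "",
        "Background letter frequencies", "A 0.25 C 0.25 G 0.25 T 0.25", "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {profile.length} "
        f"nsites= {profile.n_sequences} E= 0",
    ]
    for row in freqs:
        lines.append(" ".join(f"{x:.6f}" for x in row))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every tunable of the pipeline stages, with field-rule defaults:
    5-kb hit merging, 5000-bp flank comparison, 50-bp TSD flanks, 93-bp TSM
    window (50 + 43), 100-bp TIR segments, 40-bp terminal segment, and a
    substitution rate of 0.016 per site per Myr for dating."""

    # detection
    min_word: int = 11
    min_identity: float = 0.75
    min_length: int = 50
    merge_max_gap: int = 5000
    # TIR / TSD resolution
    tir_max_flank: int = 5000
    min_tir_len: int = 30
    min_tir_identity: float = 0.80
    tsd_flank: int = 50
    tsd_max_len: int = 8
    tsd_min_len: int = 5
    tsd_max_mismatch: int = 1
    boundary_max_shift: int = 8
    # classification
    nearly_complete_frac: float = 0.95
    min_tpase_frac: float = 0.05
    # per-copy annotation
    at_window: int = 100
    at_frac: float = 0.8
    tr_min_period: int = 20
    tr_min_copies: float = 1.8
    tr_min_identity: float = 0.8
    # motif
    tsm_upstream: int = 50
    tsm_downstream: int = 43
    min_complementarity: float = 0.5
    # divergence
    tir_segment_length: int = 100
    terminal_segment_length: int = 40
    substitution_rate_per_myr: float = 0.016

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)  # type: ignore[arg-type]

    def to_dict(self) -> dict[str, object]:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    stage: str
    config_hash: str
    seed: int | None
    input_digests: dict[str, str] = field(default_factory=dict)
    tool_version: str = ""
    record_counts: dict[str, int] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True) + "\n")


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
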