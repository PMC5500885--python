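"""File formats: FASTA haplotypes/alignments, fragment TSV/SAM, masks,
distance tables and JSON reports.

All user-facing coordinates are 1-based inclusive. Sequences are upper-cased
on read and U is normalised to T; in alignment mode gaps ('-') are kept, in
haplotype mode they are normalised to N.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AlignedFragment, Haplotype
from .consensus import Consensus
from .diversity import AlignmentMatrix

__all__ = [
    "read_fasta",
    "write_fasta",
    "load_alignment_fasta",
    "write_fragments_tsv",
    "read_fragments_tsv",
    "write_fragments_sam",
    "read_fragments_sam",
    "write_consensus",
    "write_masks_tsv",
    "write_json",
]

_ALLOWED = set("ACGTN")


def _normalise(seq: str, keep_gaps: bool) -> str:
    s = seq.upper().replace("U", "T")
    if not keep_gaps:
        s = s.replace("-", "N")
    extra = set(s) - (_ALLOWED | ({"-"} if keep_gaps else set()))
    if extra:
        # IUPAC ambiguity codes and anything else collapse to N
        for ch in extra:
            s = s.replace(ch, "N")
    return s


def read_fasta(path, circular: bool = True) -> list[Haplotype]:
    """Read haplotypes from FASTA; gaps and ambiguity codes become N."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [
        Haplotype(id=r.id, seq=_normalise(str(r.seq), keep_gaps=False), circular=circular)
        for r in records
    ]


def write_fasta(haplotypes: list[Haplotype], path) -> None:
    records = [SeqRecord(Seq(h.seq), id=h.id, description="") for h in haplotypes]
    SeqIO.write(records, str(path), "fasta")


def load_alignment_fasta(path, groups: dict | None = None) -> AlignmentMatrix:
    """Read an aligned multi-FASTA into an AlignmentMatrix.

    Sequences are upper-cased and U->T normalised; gaps are preserved. A
    ragged alignment raises an error naming the offending records.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    rows = [_normalise(str(r.seq), keep_gaps=True) for r in records]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        L = len(rows[0])
        bad = [i for i, r in zip(ids, rows) if len(r) != L]
        raise ValueError(f"ragged alignment in {path}; offending records: {bad}")
    return AlignmentMatrix(ids=ids, rows=rows, groups=groups or {})


def _quals_to_str(quals: np.ndarray) -> str:
    return "".join(chr(int(q) + 33) for q in quals)


def _quals_from_str(s: str) -> np.ndarray:
    return np.array([ord(c) - 33 for c in s], dtype=np.int32)


def write_fragments_tsv(fragments: list[AlignedFragment], path) -> None:
    """Internal fragment table: start, strand, bases, Phred+33 quals, truth
    source and per-base damage flags (0/1 string)."""
    rows = [
        {
            "start": fr.start,
            "strand": fr.strand,
            "bases": fr.bases,
            "quals": _quals_to_str(fr.quals),
            "source": fr.source,
            "damage_flags": (
                "".join("1" if d else "0" for d in fr.damage_flags)
                if fr.damage_flags is not None
                else ""
            ),
        }
        for fr in fragments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fragments_tsv(path) -> list[AlignedFragment]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        flags = (
            np.array([c == "1" for c in row.damage_flags])
            if row.damage_flags
            else None
        )
        out.append(
            AlignedFragment(
                start=int(row.start),
                strand=row.strand,
                bases=row.bases,
                quals=_quals_from_str(row.quals),
                source=row.source,
                damage_flags=flags,
            )
        )
    return out


def write_fragments_sam(
    fragments: list[AlignedFragment], path, L: int, ref_name: str = "mt"
) -> None:
    """Export fragments as plain-text SAM on a linearised circular reference.

    Fragments wrapping the origin are split into two lines; the wrapped tail
    carries the supplementary-alignment flag. The simulation truth source is
    kept in the ZS tag so round-trips preserve it.
    """
    header = {"HD": {"VN": "1.6", "SO": "unknown"}, "SQ": [{"SN": ref_name, "LN": L}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for i, fr in enumerate(fragments):
            pieces = []
            end = fr.start + len(fr) - 1
            if end <= L:
                pieces.append((fr.start, fr.bases, fr.quals, False))
            else:
                head = L - fr.start + 1
                pieces.append((fr.start, fr.bases[:head], fr.quals[:head], False))
                pieces.append((1, fr.bases[head:], fr.quals[head:], True))
            for start, bases, quals, wrapped in pieces:
                a = pysam.AlignedSegment()
                a.query_name = f"frag{i}"
                a.query_sequence = bases
                a.query_qualities = pysam.qualitystring_to_array(
                    _quals_to_str(quals)
                )
                a.reference_id = 0
                a.reference_start = start - 1  # SAM API is 0-based
                a.cigarstring = f"{len(bases)}M"
                a.mapping_quality = 60
                a.flag = (16 if fr.strand == "-" else 0) | (2048 if wrapped else 0)
                a.set_tag("ZS", fr.source)
                sam.write(a)


def read_fragments_sam(path) -> list[AlignedFragment]:
    """Ingest aligned fragments from SAM. Wrapped tails written by
    :func:`write_fragments_sam` are re-joined with their head line."""
    heads: dict[str, AlignedFragment] = {}
    tails: dict[str, tuple] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for a in sam:
            if a.is_unmapped:
                continue
            quals = np.array(a.query_qualities, dtype=np.int32)
            source = a.get_tag("ZS") if a.has_tag("ZS") else "unknown"
            if a.is_supplementary:
                tails[a.query_name] = (a.query_sequence, quals)
            else:
                heads[a.query_name] = AlignedFragment(
                    start=a.reference_start + 1,
                    strand="-" if a.is_reverse else "+",
                    bases=a.query_sequence,
                    quals=quals,
                    source=source,
                )
    out = []
    for name, fr in heads.items():
        if name in tails:
            tb, tq = tails[name]
            fr = AlignedFragment(
                start=fr.start,
                strand=fr.strand,
                bases=fr.bases + tb,
                quals=np.concatenate([fr.quals, tq]),
                source=fr.source,
            )
        out.append(fr)
    return out


def write_consensus(consensus: Consensus, path_fasta, path_posterior=None, id="consensus"):
    """Consensus FASTA plus optional per-site posterior TSV (1-based)."""
    write_fasta([Haplotype(id=id, seq=consensus.seq)], path_fasta)
    if path_posterior is not None:
        pd.DataFrame(
            {
                "position": np.arange(1, len(consensus) + 1),
                "base": list(consensus.seq),
                "posterior": consensus.posterior,
            }
        ).to_csv(path_posterior, sep="\t", index=False, float_format="%.6g")


def write_masks_tsv(annotations: list[tuple], path) -> None:
    """Masked regions as a 1-based inclusive TSV (start, end, label)."""
    pd.DataFrame(annotations, columns=["start", "end", "label"]).to_csv(
        path, sep="\t", index=False
    )


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
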