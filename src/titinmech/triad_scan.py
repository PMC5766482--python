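"""Cysteine-triad scanning of titin Ig domain sequences.

Each Ig domain sequence is globally aligned to the I91 reference module
(pdb 1TIT numbering); cysteines mapping near the reference columns 23,
73 and 80 are called CysB, CysF and CysG, and the domain is classified
by which members of the triad it carries.  Conservation profiles and
per-isoform composition tables reproduce the whole-molecule statistics
of the scan.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

#: reference columns (1-based, I91 numbering) of the conserved triad
CYS_B_COL, CYS_F_COL, CYS_G_COL = 23, 73, 80
#: strictly conserved tryptophan used as a sanity check on annotations
TRP_COL = 35

REGIONS = ("Z-disk", "I-band", "A-band", "M-band")

#: approximate band boundaries (1-based, inclusive) in canonical titin;
#: editable — supplied to region assignment as a config table
DEFAULT_REGION_TABLE = {
    "Z-disk": (1, 2100),
    "I-band": (2101, 14500),
    "A-band": (14501, 33200),
    "M-band": (33201, 40000),
}


class TriadClass(enum.Enum):
    TRIAD = "TRIAD"
    PAIR_BF = "PAIR_BF"
    PAIR_FG = "PAIR_FG"
    PAIR_BG = "PAIR_BG"
    SINGLE_B = "SINGLE_B"
    SINGLE_F = "SINGLE_F"
    SINGLE_G = "SINGLE_G"
    NONE = "NONE"


_CLASS_BY_SET = {
    frozenset("BFG"): TriadClass.TRIAD,
    frozenset("BF"): TriadClass.PAIR_BF,
    frozenset("FG"): TriadClass.PAIR_FG,
    frozenset("BG"): TriadClass.PAIR_BG,
    frozenset("B"): TriadClass.SINGLE_B,
    frozenset("F"): TriadClass.SINGLE_F,
    frozenset("G"): TriadClass.SINGLE_G,
    frozenset(): TriadClass.NONE,
}


@dataclass(frozen=True)
class DomainAnnotation:
    id: str
    start: int   # 1-based inclusive
    end: int     # 1-based inclusive
    region: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.id}: start must be < end")
        if self.region not in REGIONS:
            raise ValueError(f"{self.id}: unknown region {self.region!r}")


@dataclass(frozen=True)
class AlignmentMap:
    """Monotone mapping of 1-based domain positions to reference columns."""

    to_reference: dict      # domain position -> reference column
    score: float
    classifiable: bool = True


@dataclass(frozen=True)
class DomainClassification:
    id: str
    triad_class: TriadClass
    matched: dict                    # "B"/"F"/"G" -> domain position
    other_cysteines: tuple           # reference columns of unmatched Cys
    region: str = "I-band"


def reference_sequence() -> str:
    """The packaged 89-residue I91 reference module."""
    ref = resources.files("titinmech.data") / "i91_reference.fasta"
    with resources.as_file(ref) as path:
        record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq)


def manual_ig_table() -> pd.DataFrame:
    """The 12 manually curated Ig domains missing from automatic
    annotation of the canonical titin sequence (1-based coordinates)."""
    ref = resources.files("titinmech.data") / "manual_ig_domains.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def assign_region(start: int, end: int,
                  region_table: dict | None = None) -> str:
    table = region_table or DEFAULT_REGION_TABLE
    mid = (start + end) // 2
    for region, (lo, hi) in table.items():
        if lo <= mid <= hi:
            return region
    raise ValueError(f"position {mid} outside all region boundaries")


# ---------------------------------------------------------------------------

def load_domains(fasta_path, annotation_table) -> list[tuple[DomainAnnotation, str]]:
    """Extract annotated domain subsequences from a parent FASTA.

    `annotation_table` is a TSV path or DataFrame with columns
    id/start/end[/region] (1-based inclusive).  Each extracted domain is
    checked for the strictly conserved tryptophan near reference
    column 35; a warning (not an error) is emitted when absent.
    """
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    seq = str(record.seq)
    if isinstance(annotation_table, (str,)) or hasattr(annotation_table, "__fspath__"):
        table = pd.read_csv(annotation_table, sep="\t")
    else:
        table = annotation_table
    out = []
    for row in table.itertuples(index=False):
        region = getattr(row, "region", None) or assign_region(row.start, row.end)
        ann = DomainAnnotation(id=str(row.id), start=int(row.start),
                               end=int(row.end), region=region)
        if ann.end > len(seq) or ann.start < 1:
            raise ValueError(
                f"domain {ann.id}: annotation {ann.start}-{ann.end} outside "
                f"sequence of length {len(seq)}")
        sub = seq[ann.start - 1:ann.end]
        w_lo = max(0, TRP_COL - 11)
        w_hi = min(len(sub), TRP_COL + 9)
        if "W" not in sub[w_lo:w_hi]:
            warnings.warn(
                f"domain {ann.id}: conserved tryptophan not found near "
                f"position {TRP_COL}", stacklevel=2)
        out.append((ann, sub))
    return out


def _aligner(gap_open: float, gap_extend: float, matrix: str) -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "global"
    aln.substitution_matrix = substitution_matrices.load(matrix)
    aln.open_gap_score = -gap_open
    aln.extend_gap_score = -gap_extend
    # soft end gaps: domains may carry short flanks
    new_names = ("open_end_insertion_score", "extend_end_insertion_score",
                 "open_end_deletion_score", "extend_end_deletion_score")
    old_names = ("target_end_open_gap_score", "target_end_extend_gap_score",
                 "query_end_open_gap_score", "query_end_extend_gap_score")
    names = new_names if hasattr(aln, new_names[0]) else old_names
    for name in names:
        setattr(aln, name, 0.0)
    return aln


def map_to_reference(domain_seq: str, ref_seq: str | None = None,
                     gap_open: float = 11.0, gap_extend: float = 1.0,
                     matrix: str = "BLOSUM62",
                     score_floor: float = 0.0) -> AlignmentMap:
    """Globally align a domain to the reference and return the column map.

    Deterministic: Biopython enumerates co-optimal alignments in a fixed
    order and the first (leftmost-gap) one is used.  Alignments scoring
    at or below `score_floor` are flagged unclassifiable.
    """
    ref_seq = ref_seq or reference_sequence()
    if not domain_seq or not ref_seq:
        raise ValueError("sequences must be non-empty")
    aln = _aligner(gap_open, gap_extend, matrix)
    best = aln.align(domain_seq.upper(), ref_seq.upper())[0]
    mapping: dict[int, int] = {}
    q_blocks, r_blocks = best.aligned
    for (q0, q1), (r0, r1) in zip(q_blocks, r_blocks):
        for off in range(q1 - q0):
            mapping[q0 + off + 1] = r0 + off + 1  # 1-based
    return AlignmentMap(to_reference=mapping, score=float(best.score),
                        classifiable=float(best.score) > score_floor)


def classify_domain(amap: AlignmentMap, domain_seq: str,
                    tolerance_columns: int = 2,
                    domain_id: str = "", region: str = "I-band") -> DomainClassification:
    """Call CysB/F/G from mapped cysteine columns and classify the domain.

    A cysteine counts as a triad member when its reference column lies
    within +/- `tolerance_columns` of 23/73/80; each triad slot takes the
    nearest available cysteine.
    """
    cys_positions = [i + 1 for i, a in enumerate(domain_seq.upper()) if a == "C"]
    mapped = [(p, amap.to_reference.get(p)) for p in cys_positions]
    matched: dict[str, int] = {}
    used: set[int] = set()
    for label, col in (("B", CYS_B_COL), ("F", CYS_F_COL), ("G", CYS_G_COL)):
        best_pos, best_d = None, tolerance_columns + 1
        for p, c in mapped:
            if c is None or p in used:
                continue
            d = abs(c - col)
            if d < best_d:
                best_pos, best_d = p, d
        if best_pos is not None:
            matched[label] = best_pos
            used.add(best_pos)
    others = tuple(c for p, c in mapped if p not in used and c is not None)
    cls = _CLASS_BY_SET[frozenset(matched)] if amap.classifiable else TriadClass.NONE
    return DomainClassification(id=domain_id, triad_class=cls, matched=matched,
                                other_cysteines=others, region=region)


def scan_domains(domains, ref_seq: str | None = None,
                 tolerance_columns: int = 2, **align_kw) -> list[DomainClassification]:
    """Align and classify a list of (DomainAnnotation, sequence) pairs."""
    ref_seq = ref_seq or reference_sequence()
    out = []
    for ann, seq in domains:
        amap = map_to_reference(seq, ref_seq, **align_kw)
        out.append(classify_domain(amap, seq, tolerance_columns,
                                   domain_id=ann.id, region=ann.region))
    return out


def conservation_profile(domains, classifications=None,
                         region: str | None = None,
                         ref_seq: str | None = None, **align_kw) -> pd.DataFrame:
    """Per-reference-column cysteine frequency across domains.

    Returns a DataFrame with columns `column` (1-based reference
    position) and `frequency` (fraction of selected domains with a
    cysteine mapping there).  `region` filters (e.g. "I-band"); None
    keeps all.
    """
    ref_seq = ref_seq or reference_sequence()
    sel = [(ann, seq) for ann, seq in domains
           if region is None or ann.region == region]
    if not sel:
        raise ValueError("no domains selected for the conservation profile")
    counts = np.zeros(len(ref_seq))
    for ann, seq in sel:
        amap = map_to_reference(seq, ref_seq, **align_kw)
        cols = {amap.to_reference.get(i + 1)
                for i, a in enumerate(seq.upper()) if a == "C"}
        for c in cols:
            if c is not None:
                counts[c - 1] += 1
    return pd.DataFrame({"column": np.arange(1, len(ref_seq) + 1),
                         "frequency": counts / len(sel)})


def isoform_composition(classifications, i_band_only: bool = True,
                        isoform_name: str = "N2BA") -> dict:
    """Count table of triad classes (optionally restricted to the I-band).

    Reports the pair classes both individually and as one pooled "PAIR"
    tally, plus the triad fraction.
    """
    sel = [c for c in classifications
           if (not i_band_only) or c.region == "I-band"]
    counts = {cls.value: 0 for cls in TriadClass}
    for c in sel:
        counts[c.triad_class.value] += 1
    n = len(sel)
    singles = counts["SINGLE_B"] + counts["SINGLE_F"] + counts["SINGLE_G"]
    pairs = counts["PAIR_BF"] + counts["PAIR_FG"] + counts["PAIR_BG"]
    return {
        "isoform": isoform_name,
        "n_domains": n,
        "counts": counts,
        "n_pair": pairs,
        "n_single": singles,
        "triad_fraction": counts["TRIAD"] / n if n else float("nan"),
    }
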