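"""Extended E-box classification of peak sequences.

bHLH-LZ factors of the MiT/TFE family read 6-bp E-box cores (CACGTG and
CATGTG) together with their flanking bases: a 5' T strongly favours binding
and the 3' base separates the palindromic CLEAR-box (TCACGTGA) from
differentiation-associated M-box-like elements (TCATGTGA / TCATGTGB). Each
peak sequence is scanned on both strands and assigned exactly one class by
priority:

    TCACGTGA > TCACGTGB > TCATGTGA > TCATGTGB > CACGTG_other > CATGTG_other > none

where B is any base but A (IUPAC). Cores at a sequence edge that lack a
flank, or whose flank is N, fall to the ``_other`` class of their core. The
classification is strand-symmetric by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MOTIF_CLASSES",
    "PeakSeq",
    "MotifClass",
    "classify_peak_ebox",
    "motif_ratio_table",
    "motif_incidence_moving_avg",
    "read_peaks",
    "reverse_complement",
]

#: Class labels in priority order, highest first ("none" is the fallback).
MOTIF_CLASSES = (
    "TCACGTGA",
    "TCACGTGB",
    "TCATGTGA",
    "TCATGTGB",
    "CACGTG_other",
    "CATGTG_other",
    "none",
)

_CORES = ("CACGTG", "CATGTG")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PeakSeq:
    """A scored peak interval (0-based half-open) with its sequence."""

    chrom: str
    start: int
    end: int
    score: float
    seq: str
    name: str = "."

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if len(self.seq) != self.end - self.start:
            raise ValueError("sequence length must equal end - start")
        bad = set(self.seq) - _VALID
        if bad:
            raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")


@dataclass(frozen=True)
class MotifClass:
    """Assigned E-box class with the match location.

    ``position`` is the plus-strand 0-based start of the 6-bp core (None for
    class "none"); ``strand`` is the strand on which the classified reading
    was found.
    """

    label: str
    position: int | None = None
    strand: str | None = None


def _occurrence_label(s: str, i: int, core: str) -> str:
    """Class of the core occurrence at index i of strand-sequence s."""
    f5 = s[i - 1] if i > 0 else None
    f3 = s[i + 6] if i + 6 < len(s) else None
    other = f"{core}_other"
    if f5 != "T" or f3 is None or f3 == "N":
        return other
    if core == "CACGTG":
        return "TCACGTGA" if f3 == "A" else "TCACGTGB"
    return "TCATGTGA" if f3 == "A" else "TCATGTGB"


def classify_peak_ebox(peak: "PeakSeq | str") -> MotifClass:
    """Assign the single highest-priority E-box class of a peak sequence.

    Both strands are scanned for the CACGTG and CATGTG cores (overlapping
    occurrences included); each occurrence is labelled from its own-strand
    flanks and the best label by the priority order wins. Ties are broken by
    the leftmost core position on the plus strand, plus strand preferred.
    """
    seq = peak.seq if isinstance(peak, PeakSeq) else peak.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    n = len(seq)
    candidates = []  # (priority, plus_position, strand_rank, label, strand)
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for core in _CORES:
            i = s.find(core)
            while i != -1:
                label = _occurrence_label(s, i, core)
                plus_pos = i if strand == "+" else n - (i + 6)
                candidates.append(
                    (MOTIF_CLASSES.index(label), plus_pos, strand == "-", label, strand)
                )
                i = s.find(core, i + 1)
    if not candidates:
        return MotifClass("none")
    prio, pos, _, label, strand = min(candidates)
    return MotifClass(label, position=pos, strand=strand)


def motif_ratio_table(peaks: list[PeakSeq], grouping=None) -> pd.DataFrame:
    """Per-condition proportions of each E-box class (rows sum to 1).

    ``grouping`` is a parallel list of condition labels; with None all peaks
    form a single condition ``"all"``.
    """
    if not peaks:
        raise ValueError("no peaks")
    groups = list(grouping) if grouping is not None else ["all"] * len(peaks)
    if len(groups) != len(peaks):
        raise ValueError("grouping must be parallel to peaks")
    df = pd.DataFrame({
        "condition": groups,
        "class": [classify_peak_ebox(p).label for p in peaks],
    })
    table = (
        df.groupby("condition")["class"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=list(MOTIF_CLASSES), fill_value=0.0)
    )
    table.columns.name = None
    return table


def motif_incidence_moving_avg(
    peaks: list[PeakSeq],
    target_classes,
    window: int = 100,
) -> pd.DataFrame:
    """Moving-average incidence of target classes along the score ranking.

    Peaks are sorted by descending score; ``incidence`` is the indicator that
    a peak's class belongs to ``target_classes``; the moving average is
    centred over ``window`` peaks with truncated windows at the edges
    (the mean is taken over however much of the window lies in range).
    Returns a table of (rank, score, incidence, incidence_ma) with one row
    per peak.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if len(peaks) < window:
        raise ValueError(f"need at least {window} peaks for a {window}-peak window")
    target = set(target_classes)
    unknown = target - set(MOTIF_CLASSES)
    if unknown:
        raise ValueError(f"unknown motif classes {sorted(unknown)}")
    order = np.argsort([-p.score for p in peaks], kind="stable")
    rows = pd.DataFrame({
        "rank": np.arange(1, len(peaks) + 1),
        "score": [peaks[i].score for i in order],
        "incidence": [
            float(classify_peak_ebox(peaks[i]).label in target) for i in order
        ],
    })
    rows["incidence_ma"] = (
        rows["incidence"].rolling(window, center=True, min_periods=1).mean()
    )
    return rows


def read_peaks(bed_path, fasta_path) -> list[PeakSeq]:
    """Load peaks from a BED6 file plus a FASTA.

    The FASTA may either be a genome (records named by chromosome, sequences
    extracted by interval) or a per-peak FASTA whose records are named after
    the BED name column.
    """
    from Bio import SeqIO

    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    peaks = []
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"BED6 line with fewer than 5 columns: {line!r}")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4])
            if chrom in records:
                seq = records[chrom][start:end]
            elif name in records:
                seq = records[name]
            else:
                raise KeyError(
                    f"no FASTA record for chromosome {chrom!r} or peak name {name!r}"
                )
            peaks.append(PeakSeq(chrom=chrom, start=start, end=end, score=score,
                                 seq=seq, name=name))
    return peaks


def write_peaks(peaks: list[PeakSeq], bed_path, fasta_path) -> None:
    """Write peaks as a BED6 + per-peak FASTA pair."""
    with open(bed_path, "w") as bed, open(fasta_path, "w") as fa:
        for i, p in enumerate(peaks):
            name = p.name if p.name != "." else f"peak_{i}"
            bed.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.score:g}\t.\n")
            fa.write(f">{name}\n{p.seq}\n")
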