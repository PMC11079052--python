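"""Satellite-DNA sequence analyses: GC content, methylation-sensitive digests,
probe matching and tandem-repeat structure.

Mouse chromocenters sit on pericentromeric major-satellite arrays that are
heavily CpG-methylated; a methylation-sensitive enzyme (HpyCH4IV, HpaII)
therefore cuts them rarely while its methylation-insensitive counterpart
(ApoI, MspI) produces the expected short-fragment ladder.  These operations
simulate that digest logic on sequences carrying an explicit CpG methylation
mask, and characterise the tandem-repeat structure of probe sequences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import edlib
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .synthetic import MethylatedSequence

__all__ = [
    "MethylatedSequence",
    "RestrictionEnzyme",
    "DigestResult",
    "TandemStructure",
    "ENZYMES",
    "gc_content",
    "find_sites",
    "digest",
    "count_probe_matches",
    "tandem_structure",
    "load_probe",
    "reverse_complement",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme with an IUPAC site and CpG-methylation sensitivity.

    ``cut_offset`` is the between-base index of the top-strand cut within the
    recognition site; a ``blocked_by_cpg_methylation`` enzyme skips any site
    whose matched window contains a methylated CpG cytosine.
    """

    name: str
    iupac_site: str
    cut_offset: int
    blocked_by_cpg_methylation: bool

    def __post_init__(self) -> None:
        site = self.iupac_site.upper()
        if not site or any(c not in _IUPAC for c in site):
            raise ValueError(f"invalid IUPAC site {self.iupac_site!r}")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError("cut_offset must lie within the site")

    def site_regex(self) -> re.Pattern:
        pattern = "".join(
            c if len(_IUPAC[c]) == 1 else "[" + _IUPAC[c] + "]"
            for c in self.iupac_site.upper()
        )
        return re.compile(f"(?=({pattern}))")  # lookahead: overlapping matches


ENZYMES: dict[str, RestrictionEnzyme] = {
    e.name: e
    for e in [
        RestrictionEnzyme("HpyCH4IV", "ACGT", 1, blocked_by_cpg_methylation=True),
        RestrictionEnzyme("ApoI", "RAATTY", 1, blocked_by_cpg_methylation=False),
        RestrictionEnzyme("HpaII", "CCGG", 1, blocked_by_cpg_methylation=True),
        RestrictionEnzyme("MspI", "CCGG", 1, blocked_by_cpg_methylation=False),
    ]
}


def gc_content(seq: str, skip_ambiguous: bool = False) -> float:
    """Percent G+C of a sequence (case-insensitive).

    In the default strict mode any non-ACGT character raises with its
    position; with ``skip_ambiguous`` other characters are ignored in both
    numerator and denominator.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    if not skip_ambiguous:
        for i, c in enumerate(s):
            if c not in "ACGT":
                raise ValueError(f"non-ACGT character {c!r} at position {i}")
        denom = len(s)
    else:
        denom = sum(c in "ACGT" for c in s)
        if denom == 0:
            raise ValueError("no unambiguous bases")
    return 100.0 * (s.count("G") + s.count("C")) / denom


def find_sites(ms: MethylatedSequence, enz: RestrictionEnzyme) -> list[int]:
    """Top-strand scan for recognition sites; returns sorted cut positions.

    Built-in sites are palindromic, so the top strand suffices.  For a
    methylation-blocked enzyme a match is suppressed when any methylated CpG
    cytosine falls inside the matched window.
    """
    site_len = len(enz.iupac_site)
    cuts = []
    meth = ms.methylated_cpg
    for m in enz.site_regex().finditer(ms.seq):
        start = m.start()
        if enz.blocked_by_cpg_methylation and any(
            p in meth for p in range(start, start + site_len)
        ):
            continue
        cuts.append(start + enz.cut_offset)
    return sorted(set(cuts))


@dataclass
class DigestResult:
    """Cut positions and fragment lengths of a linear digest."""

    cut_positions: list[int]
    fragment_lengths: list[int]


def digest(ms: MethylatedSequence, enz: RestrictionEnzyme) -> DigestResult:
    """Digest a linear molecule; fragment lengths always sum to the length."""
    cuts = find_sites(ms, enz)
    bounds = [0] + [c for c in cuts if 0 < c < len(ms.seq)] + [len(ms.seq)]
    fragments = [b - a for a, b in zip(bounds[:-1], bounds[1:])]
    return DigestResult(cut_positions=cuts, fragment_lengths=fragments)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def count_probe_matches(seq: str, probe: str, max_mismatches: int = 0,
                        both_strands: bool = True) -> tuple[int, list[tuple[int, str]]]:
    """Sliding-window Hamming matching of a probe against a sequence.

    Counts every window (overlaps included) with at most ``max_mismatches``
    mismatches on the forward strand and, when ``both_strands``, against the
    reverse complement of the probe (positions reported on ``seq``).  Returns
    (count, [(position, strand), ...]).
    """
    seq = seq.upper()
    probe = probe.upper()
    if len(probe) > len(seq):
        raise ValueError("probe longer than sequence")
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    n, k = len(seq), len(probe)
    windows = np.lib.stride_tricks.sliding_window_view(s, k)
    queries = [("+", probe)]
    if both_strands:
        rc = reverse_complement(probe)
        if rc != probe:
            queries.append(("-", rc))
    hits = []
    for strand, q in queries:
        qa = np.frombuffer(q.encode(), dtype=np.uint8)
        mismatches = (windows != qa).sum(axis=1)
        for pos in np.flatnonzero(mismatches <= max_mismatches):
            hits.append((int(pos), strand))
    hits.sort()
    return len(hits), hits


@dataclass
class TandemStructure:
    """Detected repeat period, copy count and span of a tandem array."""

    period: int
    n_complete_copies: int
    mean_copy_identity: float
    repeat_span: tuple[int, int]  # 0-based half-open
    repetitive: bool
    unit: str = ""


def _best_period(s: np.ndarray, min_period: int, max_period: int) -> tuple[int, float]:
    """Smallest period whose mean lag identity is within 5% of the maximum.

    Multiples of the fundamental period score essentially the same identity
    (up to sampling noise), so taking the plain argmax would often return a
    harmonic; the relative tolerance recovers the fundamental.
    """
    idents = np.array([
        float((s[:-p] == s[p:]).mean()) for p in range(min_period, max_period + 1)
    ])
    cutoff = 0.95 * idents.max()
    p = min_period + int(np.argmax(idents >= cutoff))
    return p, float(idents[p - min_period])


def tandem_structure(seq: str, min_period: int = 2, max_period: int | None = None,
                     min_identity: float = 0.8) -> TandemStructure:
    """Characterise the tandem-repeat structure of a sequence.

    The period p maximises the mean per-base identity between seq[i] and
    seq[i+p] over the overlap (Hamming).  A representative unit is the
    period-length window that best matches its next copy; complete copies are
    then counted by greedy non-overlapping semi-global alignment of that unit
    (identity >= ``min_identity``), which tolerates the indels real satellite
    monomers accumulate.  When no period reaches the identity threshold the
    sequence is flagged non-repetitive with a single copy spanning itself.
    """
    seq = seq.upper()
    if set(seq) - set("ACGT"):
        raise ValueError("sequence must be strict ACGT")
    if max_period is None:
        max_period = len(seq) // 2
    if not 2 <= min_period <= max_period <= len(seq) // 2:
        raise ValueError("need 2 <= min_period <= max_period <= len(seq)/2")
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    p, _ = _best_period(s, min_period, max_period)

    # windowed lag identity: w[i] = identity of seq[i:i+p] with its next copy
    m = (s[:-p] == s[p:]).astype(float)
    if len(m) < p:
        return TandemStructure(p, 1, 0.0, (0, len(seq)), repetitive=False)
    cs = np.concatenate([[0.0], np.cumsum(m)])
    w = (cs[p:] - cs[:-p]) / p
    if w.max() < min_identity:
        return TandemStructure(p, 1, float(w.max()), (0, len(seq)), repetitive=False)

    # Candidate unit windows: each putative copy along the tiling that starts
    # at the 5' edge of the high-identity region (so a medoid copy can win),
    # plus the most self-similar window.
    run_start = int(np.argmax(w >= min_identity))
    candidates = {run_start + j * p for j in range((len(seq) - run_start) // p)}
    candidates.add(int(np.argmax(w)))
    max_ed = int((1 - min_identity) * p)
    best_hits: list[tuple[int, int, int]] = []
    best_unit = ""
    for c in candidates:
        unit = seq[c: c + p]
        work = seq
        hits: list[tuple[int, int, int]] = []
        # greedy non-overlapping alignment, best remaining hit first
        while True:
            res = edlib.align(unit, work, mode="HW", task="locations", k=max_ed)
            if res["editDistance"] == -1 or not res["locations"]:
                break
            start, end = res["locations"][0]
            hits.append((start, end + 1, res["editDistance"]))
            work = work[:start] + "N" * (end + 1 - start) + work[end + 1:]
        if len(hits) > len(best_hits) or (
            len(hits) == len(best_hits)
            and sum(h[2] for h in hits) < sum(h[2] for h in best_hits)
        ):
            best_hits, best_unit = hits, unit
    best_hits.sort()
    identities = [1.0 - ed / p for _, _, ed in best_hits]
    return TandemStructure(
        period=p,
        n_complete_copies=len(best_hits),
        mean_copy_identity=float(np.mean(identities)),
        repeat_span=(best_hits[0][0], best_hits[-1][1]),
        repetitive=True,
        unit=best_unit,
    )


def load_probe(name: str) -> str:
    """Load one of the packaged probe sequences by record id.

    Available: red_deer_satellite_I_probe, mouse_major_satellite_probe,
    mouse_major_satellite_fish_probe.
    """
    path = resources.files("chromofoci.data") / "probes.fasta"
    with path.open() as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id == name:
                return str(record.seq)
    raise KeyError(f"no packaged probe named {name!r}")
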