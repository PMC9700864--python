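"""Intact-mass assignment of fibril proteins to precursor fragments.

Amyloid fibril proteins are proteolytic fragments of their precursor.
Given the precursor sequence and a list of observed intact masses, every
candidate subsequence over a set of start/end positions is enumerated and
each observed mass is assigned to all candidates within a ppm tolerance.
Multiple assignments per mass are reported (and ranked), mirroring the
ambiguity real intact-mass data can have when homologous precursors share
local sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from pyteomics import mass as _pmass

WATER_MONO_DA = float(_pmass.calculate_mass(formula="H2O"))        # 18.0105646...
WATER_AVG_DA = float(_pmass.calculate_mass(formula="H2O", average=True))

_VALID = set("ACDEFGHIKLMNPQRSTVWY")


def peptide_mass(sequence: str, kind: str = "monoisotopic") -> float:
    """Neutral peptide mass in Da (residue masses plus one water)."""
    if not sequence:
        raise ValueError("empty sequence")
    bad = [(i + 1, a) for i, a in enumerate(sequence) if a not in _VALID]
    if bad:
        raise ValueError(f"nonstandard letter {bad[0][1]!r} at position {bad[0][0]}")
    if kind == "monoisotopic":
        return float(_pmass.fast_mass(sequence))
    if kind == "average":
        return float(_pmass.calculate_mass(sequence=sequence, average=True))
    raise ValueError(f"unknown mass kind {kind!r}")


@dataclass(frozen=True)
class FragmentCandidate:
    start: int  # 1-based inclusive
    end: int
    sequence: str
    mass_mono_Da: float
    mass_avg_Da: float


@dataclass(frozen=True)
class FragmentMatch:
    observed_mass_Da: float
    candidate: FragmentCandidate
    error_ppm: float  # 1e6 * (observed - theoretical) / theoretical
    rank: int


def enumerate_fragments(precursor: str, start_positions, end_positions
                        ) -> list[FragmentCandidate]:
    """All precursor[start..end] candidates over the Cartesian product of
    positions (1-based inclusive, start <= end), in (start, end) order."""
    starts = sorted(set(int(s) for s in start_positions))
    ends = sorted(set(int(e) for e in end_positions))
    if not starts or not ends:
        raise ValueError("start/end position sets must be non-empty")
    if starts[0] < 1 or ends[-1] > len(precursor):
        raise ValueError("positions outside the precursor sequence")
    out = []
    for s, e in product(starts, ends):
        if s > e:
            continue
        seq = precursor[s - 1:e]
        out.append(FragmentCandidate(
            start=s, end=e, sequence=seq,
            mass_mono_Da=peptide_mass(seq, "monoisotopic"),
            mass_avg_Da=peptide_mass(seq, "average")))
    return out


def match_masses(observed, candidates, tolerance_ppm: float = 10.0,
                 kind: str = "monoisotopic",
                 modification_Da: float = 0.0):
    """Assign observed masses to candidates within a ppm tolerance.

    Every (observed, candidate) pair within tolerance is reported;
    matches for one observed mass are ranked by |error_ppm|, ties broken
    by shorter fragment then smaller start.  ``modification_Da`` is an
    optional fixed mass offset added to every theoretical mass.

    Returns (matches, unmatched_observed).
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    attr = "mass_mono_Da" if kind == "monoisotopic" else "mass_avg_Da"
    matches: list[FragmentMatch] = []
    unmatched = []
    for obs in observed:
        hits = []
        for cand in candidates:
            theo = getattr(cand, attr) + modification_Da
            ppm = 1e6 * (obs - theo) / theo
            if abs(ppm) <= tolerance_ppm:
                hits.append((cand, ppm))
        if not hits:
            unmatched.append(float(obs))
            continue
        hits.sort(key=lambda h: (abs(h[1]), h[0].end - h[0].start, h[0].start))
        for rank, (cand, ppm) in enumerate(hits, start=1):
            matches.append(FragmentMatch(float(obs), cand, float(ppm), rank))
    return matches, unmatched


def recall(matches, truth) -> float:
    """Fraction of true (start, end) ranges recovered as rank-1 matches of
    their observed mass (evaluation helper for synthetic fixtures)."""
    if not truth:
        raise ValueError("empty truth list")
    best = {}
    for m in matches:
        if m.rank == 1:
            best.setdefault(round(m.observed_mass_Da, 6), set()).add(
                (m.candidate.start, m.candidate.end))
    # truth order corresponds to fixture emission order; compare as sets of
    # ranges recovered anywhere among rank-1 assignments
    recovered = set().union(*best.values()) if best else set()
    return sum(1 for t in truth if t in recovered) / len(truth)
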