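"""Pairing of LxVP docking sites with downstream [S/T]xxP substrate sites.

A phosphosite is CN-accessible only if the stretch between the LxVP docking
pocket and the active site can be bridged, which requires at least 9
intervening residues.  This module pairs LxVP hits with [S/T]xxP hits under
that geometric constraint and computes cohort statistics: the fractions of
pairings whose separation falls in the 10-35 and 10-100 residue windows,
sites per protein, and the Ser/Thr split of the anchors.

Separation is measured from the last residue of the LxVP match to the
[S/T]xxP anchor residue (``stxxp.anchor - lxvp.end``), matching the
physical argument of bridging the LxVP pocket to the active site; the
distinct :func:`linker_length` counts residues strictly between two motifs
(e.g. 27 between the NHE1 LxVP ending at 687 and the PxIxIT starting at
715).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable

from .motifs import MotifHit

DEFAULT_MIN_SEPARATION = 9
WINDOW_NEAR = (10, 35)
WINDOW_FAR = (10, 100)


class MotifOrderError(ValueError):
    """Motifs overlap or are mis-ordered for a linker computation."""


@dataclass(frozen=True)
class SitePairing:
    protein_id: str
    lxvp_hit: MotifHit
    stxxp_hit: MotifHit
    separation: int

    @property
    def anchor_letter(self) -> str:
        return self.stxxp_hit.anchor_letter


@dataclass
class CohortSummary:
    n_proteins_with_both: int
    sites_per_protein: dict
    frac_sep_10_35: float
    frac_sep_10_100: float
    ser_count: int
    thr_count: int
    n_pairings: int
    counting: str = "all_pairs"

    def as_dict(self) -> dict:
        return {
            "counting": self.counting,
            "n_proteins_with_both": self.n_proteins_with_both,
            "sites_per_protein": dict(self.sites_per_protein),
            "frac_sep_10_35": self.frac_sep_10_35,
            "frac_sep_10_100": self.frac_sep_10_100,
            "ser_count": self.ser_count,
            "thr_count": self.thr_count,
            "n_pairings": self.n_pairings,
        }


def linker_length(upstream: MotifHit, downstream: MotifHit) -> int:
    """Count of residues strictly between two ordered motifs.

    Raises :class:`MotifOrderError` unless ``upstream.end < downstream.start``.
    """
    if upstream.end >= downstream.start:
        raise MotifOrderError(
            f"motifs overlap or are mis-ordered: upstream ends at {upstream.end}, "
            f"downstream starts at {downstream.start}"
        )
    return downstream.start - upstream.end - 1


def pair_lxvp_stxxp(
    lxvp_hits: Iterable[MotifHit],
    stxxp_hits: Iterable[MotifHit],
    min_separation: int = DEFAULT_MIN_SEPARATION,
    direction: str = "c_terminal_only",
) -> list:
    """All qualifying (LxVP, [S/T]xxP) pairs on one protein.

    Default mode pairs each LxVP with every [S/T]xxP whose anchor lies
    C-terminal to the LxVP span at separation >= ``min_separation``; an
    [S/T]xxP may pair with multiple LxVPs and vice versa.  ``direction='both'``
    additionally admits N-terminal sites (separation measured symmetrically,
    from the LxVP start back to the anchor).
    """
    if direction not in ("c_terminal_only", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    lxvp_hits = list(lxvp_hits)
    stxxp_hits = list(stxxp_hits)
    ids = {h.protein_id for h in lxvp_hits} | {h.protein_id for h in stxxp_hits}
    if len(ids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(ids)}")
    pairings = []
    for lx in lxvp_hits:
        for st in stxxp_hits:
            if st.anchor > lx.end:
                sep = st.anchor - lx.end
            elif direction == "both" and st.anchor < lx.start:
                sep = lx.start - st.anchor
            else:
                continue
            if sep >= min_separation:
                pairings.append(
                    SitePairing(
                        protein_id=lx.protein_id,
                        lxvp_hit=lx,
                        stxxp_hit=st,
                        separation=sep,
                    )
                )
    pairings.sort(key=lambda p: (p.lxvp_hit.start, p.stxxp_hit.anchor))
    return pairings


def _window_fraction(separations, window) -> float:
    lo, hi = window
    if not separations:
        return 0.0
    return sum(lo <= s <= hi for s in separations) / len(separations)


def summarize_cohort(
    pairings: Iterable[SitePairing], counting: str = "all_pairs"
) -> CohortSummary:
    """Cohort statistics over pairings from one or more proteins.

    ``counting='all_pairs'`` uses every pairing; ``counting='nearest_lxvp'``
    keeps, for each distinct [S/T]xxP site, only its closest LxVP (how the
    per-site distance distribution of a screen is usually reported).
    Window fractions use closed intervals [10, 35] and [10, 100].
    """
    if counting not in ("all_pairs", "nearest_lxvp"):
        raise ValueError(f"unknown counting {counting!r}")
    pairings = list(pairings)
    if counting == "nearest_lxvp":
        best = {}
        for p in pairings:
            key = (p.protein_id, p.stxxp_hit.anchor)
            if key not in best or p.separation < best[key].separation:
                best[key] = p
        pairings = list(best.values())
    per_protein = defaultdict(int)
    for p in pairings:
        per_protein[p.protein_id] += 1
    seps = [p.separation for p in pairings]
    letters = [p.anchor_letter for p in pairings]
    return CohortSummary(
        n_proteins_with_both=len(per_protein),
        sites_per_protein=dict(per_protein),
        frac_sep_10_35=_window_fraction(seps, WINDOW_NEAR),
        frac_sep_10_100=_window_fraction(seps, WINDOW_FAR),
        ser_count=letters.count("S"),
        thr_count=letters.count("T"),
        n_pairings=len(pairings),
        counting=counting,
    )
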