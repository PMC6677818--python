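"""Synthetic inputs with planted ground truth for every pipeline stage.

Four generators emulate the statistical structure of the study's data:

* ``gen_screen_dataset`` — protein sequences carrying a planted LxVP
  docking site and downstream [S/T]xxP sites at controlled separations,
  inside a high-disorder stretch (scores >= 0.45) against an ordered
  background (scores <= 0.2), so the 0.4 disorder threshold is decisive.
  Decoy motifs can be planted in ordered regions to exercise the filter.
* ``gen_timecourses`` — single-exponential decay peaks plus complementary
  "reporting neighbor" rise peaks per phosphosite, with Gaussian noise;
  CN-resistant sites are planted at k = 0 (constant intensity).
* ``gen_itc`` — single-site Wiseman isotherms on a 25-injection schedule.
* ``gen_pnpp`` — Michaelis-Menten saturation curves on a 0-8000 uM grid.

Every generator takes an explicit seed and is bit-reproducible; each
returns its inputs together with a truth table of the planted parameters.

Planted LxVP instances are sampled so that they can never contain or
complete an unplanned [S/T]xxP match (no S/T at the set/wildcard positions,
no P at wildcards); any accidental motif arising from the uniform random
background is scrubbed by mutating a non-planted position to G, keeping the
truth table exact by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import binding, kinetics
from .disorder import DisorderTrack
from .motifs import AA20, LXVP_CN, STXXP, MotifPattern, ProteinRecord, scan_sequence

# ---------------------------------------------------------------------------
# Printed NHE1 fragments (in-package fixture; coordinates are the protein's own)
# ---------------------------------------------------------------------------

NHE1_FRAGMENTS = {
    "lxvp": ProteinRecord("NHE1_681", "NNYLTVP", 681),
    "pxixit": ProteinRecord("NHE1_715", "PVITIDPA", 715),
    "phosphosite_wt": ProteinRecord("NHE1_771", "SPGTDDVFTPAPSDSPS", 771),
    "phosphosite_s785t": ProteinRecord("NHE1_777_S785T", "VFTPAPSDTPSSQRIQ", 777),
    "phosphosite_s785t_s787a_s788p": ProteinRecord(
        "NHE1_777_S785T_S787A_S788P", "VFTPAPSDTPAPQRIQ", 777
    ),
    "rar": ProteinRecord("NHE1_698", "RAR", 698),
}


def nhe1_printed_composite() -> ProteinRecord:
    """Synthetic stand-in for the NHE1 tail assembled from printed fragments.

    Places each packaged fragment at its own residue numbering on a glycine
    filler spanning 681-792.  This is NOT the real NHE1 sequence — only the
    printed fragments are authentic — but it carries the authentic motif
    coordinates (LxVP anchor 684, PxIxIT instance at 715, [S/T]xxP anchors
    779/783) on a single record, which is what the pairing stage needs.
    """
    start, end = 681, 792
    seq = ["G"] * (end - start + 1)
    for key in ("lxvp", "rar", "pxixit", "phosphosite_wt"):
        frag = NHE1_FRAGMENTS[key]
        i0 = frag.start_number - start
        seq[i0 : i0 + len(frag.sequence)] = list(frag.sequence)
    return ProteinRecord("NHE1ct_synthetic", "".join(seq), start)


class GenerationError(ValueError):
    """The requested plan cannot be realised (e.g. sequence too short)."""


@dataclass
class ScreenTruth:
    """Planted positions for one generated protein."""

    protein_id: str
    lxvp_span: tuple  # (start, end)
    lxvp_anchor: int
    stxxp_anchors: list  # residue numbers
    stxxp_letters: list  # 'S' or 'T' per anchor
    separations: list  # anchor - lxvp_end, per site
    idr_span: tuple
    decoy_anchors: list = field(default_factory=list)


@dataclass
class ScreenDataset:
    records: list  # ProteinRecord
    tracks: dict  # protein_id -> DisorderTrack
    truth: list  # ScreenTruth per record
    seed: int

    def truth_json(self) -> str:
        payload = {
            "seed": self.seed,
            "proteins": [
                {
                    "protein_id": t.protein_id,
                    "lxvp_span": list(t.lxvp_span),
                    "lxvp_anchor": t.lxvp_anchor,
                    "stxxp_anchors": t.stxxp_anchors,
                    "stxxp_letters": t.stxxp_letters,
                    "separations": t.separations,
                    "idr_span": list(t.idr_span),
                    "decoy_anchors": t.decoy_anchors,
                }
                for t in self.truth
            ],
        }
        return json.dumps(payload, indent=1)


def _sample_lxvp_instance(rng) -> str:
    """A 6-mer matching the LxVP definition, free of S/T/P at loose positions."""
    e1 = rng.choice(sorted(set("NQDESRTH") - set("ST")))
    e2 = rng.choice(sorted(set("YTDFILV") - set("T")))
    safe_wild = sorted(set(AA20) - set("STP"))
    return "".join(
        [e1, e2, "L", rng.choice(safe_wild), rng.choice(["V", "L"]), rng.choice(safe_wild)]
    )


def _sample_stxxp_instance(rng) -> str:
    safe_wild = sorted(set(AA20) - set("P"))
    return "".join(
        [rng.choice(["S", "T"]), rng.choice(safe_wild), rng.choice(safe_wild), "P"]
    )


def _scrub_accidental(seq: list, protected: set, rng) -> None:
    """Mutate non-planted motif matches to G until none remain.

    G belongs to no position class of either pattern, so setting a
    non-wildcard position to G destroys the match and can never create a
    new one; wildcard positions are never targeted (G would still match).
    """
    for _ in range(50):
        rec = ProteinRecord("tmp", "".join(seq), 1)
        dirty = False
        for pattern in (LXVP_CN, STXXP):
            for hit in scan_sequence(rec, pattern):
                span = set(range(hit.start, hit.end + 1))
                if span <= protected:
                    continue
                candidates = [
                    hit.start + off
                    for off, el in enumerate(pattern.elements)
                    if el is not None and (hit.start + off) not in protected
                ]
                if not candidates:
                    raise GenerationError(
                        "accidental motif pinned by planted spans; re-seed the plan"
                    )
                target = hit.anchor if hit.anchor in candidates else candidates[0]
                seq[target - 1] = "G"
                dirty = True
        if not dirty:
            return
    raise GenerationError("could not scrub accidental motifs")  # pragma: no cover


def gen_screen_dataset(
    n_proteins: int = 10,
    length: int = 300,
    sites_per_protein: int = 1,
    separation_window: tuple = (10, 35),
    n_decoys: int = 0,
    idr_pad: int = 5,
    seed: int = 0,
) -> ScreenDataset:
    """Sequences with planted LxVP + [S/T]xxP sites and a decisive IDR.

    Separations (anchor minus LxVP end) are drawn uniformly from the closed
    ``separation_window``.  The planted IDR covers the LxVP through the last
    [S/T]xxP plus ``idr_pad`` residues each side (scores in [0.5, 0.9]);
    everything else scores in [0.0, 0.2].  ``n_decoys`` [S/T]xxP instances
    are planted per protein in the ordered tail, to be removed by the 0.4
    disorder filter.
    """
    rng = np.random.default_rng(seed)
    lo, hi = separation_window
    if lo < 4:
        raise GenerationError("separations below the [S/T]xxP length are infeasible")
    needed = 10 + 6 + hi + 4 + idr_pad + 20 * (n_decoys + 1)
    if length < needed:
        raise GenerationError(f"length {length} too short for the plan (need ~{needed})")

    records, tracks, truths = [], {}, []
    for p in range(n_proteins):
        pid = f"synth{p:03d}"
        seq = list(rng.choice(list(AA20), size=length))
        lx_start = 10 + int(rng.integers(0, 5))
        lx = _sample_lxvp_instance(rng)
        seq[lx_start - 1 : lx_start + 5] = list(lx)
        lx_end = lx_start + 5
        protected = set(range(lx_start, lx_end + 1))

        # planted sites occupy anchor..anchor+3, so separations must be >=4 apart
        for attempt in range(1000):
            seps = sorted(int(s) for s in rng.integers(lo, hi + 1, size=sites_per_protein))
            if all(b - a >= 4 for a, b in zip(seps, seps[1:])):
                break
        else:
            raise GenerationError(
                f"cannot place {sites_per_protein} non-overlapping sites in "
                f"separation window {separation_window}"
            )
        anchors, letters = [], []
        for sep in seps:
            anchor = lx_end + sep
            inst = _sample_stxxp_instance(rng)
            seq[anchor - 1 : anchor + 3] = list(inst)
            anchors.append(anchor)
            letters.append(inst[0])
            protected |= set(range(anchor, anchor + 4))

        idr_start = max(1, lx_start - idr_pad)
        idr_end = min(length, anchors[-1] + 3 + idr_pad)

        decoy_anchors = []
        decoy_base = idr_end + 20
        for d in range(n_decoys):
            anchor = decoy_base + 10 * d
            if anchor + 3 > length:
                raise GenerationError("no room for decoys in the ordered tail")
            inst = _sample_stxxp_instance(rng)
            seq[anchor - 1 : anchor + 3] = list(inst)
            decoy_anchors.append(anchor)
            protected |= set(range(anchor, anchor + 4))

        _scrub_accidental(seq, protected, rng)
        sequence = "".join(seq)
        record = ProteinRecord(pid, sequence, 1)

        scores = rng.uniform(0.0, 0.2, size=length)
        scores[idr_start - 1 : idr_end] = rng.uniform(0.5, 0.9, size=idr_end - idr_start + 1)
        track = DisorderTrack(pid, list(range(1, length + 1)), list(sequence), scores)

        records.append(record)
        tracks[pid] = track
        truths.append(
            ScreenTruth(
                protein_id=pid,
                lxvp_span=(lx_start, lx_end),
                lxvp_anchor=lx_start + 2,
                stxxp_anchors=anchors,
                stxxp_letters=letters,
                separations=[a - lx_end for a in anchors],
                idr_span=(idr_start, idr_end),
                decoy_anchors=decoy_anchors,
            )
        )
    return ScreenDataset(records=records, tracks=tracks, truth=truths, seed=seed)


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

#: default time grid: 13 points over 0-48 h, matching an overnight HSQC series
DEFAULT_TIME_GRID_H = np.linspace(0.0, 48.0, 13)


def gen_timecourses(
    site_plan: dict,
    times: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    include_rise: bool = True,
    seed: int = 0,
):
    """Time courses per phosphosite from planted first-order rates.

    ``site_plan`` maps site label -> true rate in 1e-3 h^-1 (0 for a
    CN-resistant site).  Each site gets a decay peak of unit amplitude and,
    when ``include_rise`` is set, a complementary rise peak reporting the
    unphosphorylated state.  ``noise_sd`` is the Gaussian sigma as a
    fraction of the initial amplitude.  Returns (timecourses, truth dict).
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(DEFAULT_TIME_GRID_H if times is None else times, dtype=float)
    out = []
    for site, k_milli in site_plan.items():
        k = k_milli / kinetics.RATE_SCALE
        decay = kinetics.exponential_model(t, 1.0, k, 0.0, "decay")
        peaks = [(f"{site}_p", "decay", decay)]
        if include_rise:
            rise = kinetics.exponential_model(t, 1.0, k, 0.0, "rise")
            peaks.append((f"{site}_neighbor", "rise", rise))
        for peak_id, direction, clean in peaks:
            y = clean + rng.normal(0.0, noise_sd, size=len(t)) if noise_sd > 0 else clean
            out.append(
                kinetics.SiteTimeCourse(
                    site_label=site,
                    peak_id=peak_id,
                    direction=direction,
                    times=t,
                    intensities=np.clip(y, 0.0, None),
                )
            )
    truth = {"seed": seed, "noise_sd": noise_sd, "k_dephos_1e-3_per_h": dict(site_plan)}
    return out, truth


# ---------------------------------------------------------------------------
# ITC and pNPP
# ---------------------------------------------------------------------------

def gen_itc(
    n: float,
    K_D: float,
    dH: float,
    schedule: Optional[binding.ItcExperiment] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Synthetic isotherm: Wiseman forward model plus Gaussian heat noise.

    ``noise_sd`` is the sigma in ucal (absolute).  Returns (ItcExperiment
    with heats, truth dict).
    """
    rng = np.random.default_rng(seed)
    sched = schedule if schedule is not None else binding.default_schedule()
    heats = binding.wiseman_heats(n, K_D, dH, sched)
    if noise_sd > 0:
        heats = heats + rng.normal(0.0, noise_sd, size=len(heats))
    exp = binding.ItcExperiment(
        cell_concentration=sched.cell_concentration,
        syringe_concentration=sched.syringe_concentration,
        cell_volume=sched.cell_volume,
        injection_volumes=sched.injection_volumes.copy(),
        heats=heats,
        temperature=sched.temperature,
    )
    truth = {"seed": seed, "n": n, "K_D_M": K_D, "dH_kcal_per_mol": dH, "noise_sd_ucal": noise_sd}
    return exp, truth


#: substrate grid used in the colorimetric phosphatase assay
DEFAULT_PNPP_GRID_M = np.array(
    [0.0, 125, 250, 500, 1000, 2000, 3000, 4000, 6000, 8000]
) * 1e-6


def gen_pnpp(
    Km: float,
    Vmax: float,
    substrate_M: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Saturation-kinetics rate curve with Gaussian noise.

    ``noise_sd`` is the sigma as a fraction of Vmax.  Returns
    (substrate array, rate array, truth dict).
    """
    rng = np.random.default_rng(seed)
    S = np.asarray(DEFAULT_PNPP_GRID_M if substrate_M is None else substrate_M, dtype=float)
    v = binding.michaelis_menten(S, Vmax, Km)
    if noise_sd > 0:
        v = np.clip(v + rng.normal(0.0, noise_sd * Vmax, size=len(S)), 0.0, None)
    truth = {"seed": seed, "Km_M": Km, "Vmax_M_per_s": Vmax, "noise_sd_frac": noise_sd}
    return S, v, truth
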