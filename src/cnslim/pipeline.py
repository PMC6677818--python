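"""Orchestration: screening runs, recovery harness, run configuration.

``run_screen`` chains the stages scan -> disorder filter -> pair ->
summarize over a FASTA of numbered protein records plus per-protein
disorder tracks, logging per-stage counts, and emits a TSV of pairings
and a JSON summary that embeds the exact configuration used (audit trail).

``run_recover`` re-fits datasets produced by the synthetic generators and
compares the estimates against the planted truth table, with a
machine-readable pass/fail per parameter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import binding, kinetics, synthetic
from .disorder import DEFAULT_THRESHOLD, filter_hits_by_disorder, read_disorder_track
from .motifs import BUILTIN_PATTERNS, parse_pattern, read_fasta, scan_sequence
from .screen import DEFAULT_MIN_SEPARATION, pair_lxvp_stxxp, summarize_cohort

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_INPUT_ERROR = 2
EXIT_NO_CONVERGENCE = 3


@dataclass
class RunConfig:
    """Validated parameters for a screening run.

    The pattern registry defaults to the built-in LxVP / [S/T]xxP / PxIxIT
    definitions; ``lxvp_pattern`` / ``stxxp_pattern`` accept alternative
    pattern strings (anchor at the L and the S/T respectively).
    """

    fasta: Optional[str] = None
    disorder_dir: Optional[str] = None
    lxvp_pattern: Optional[str] = None
    stxxp_pattern: Optional[str] = None
    disorder_threshold: float = DEFAULT_THRESHOLD
    disorder_rule: str = "all_residues"
    min_idr_length: int = 1
    min_separation: int = DEFAULT_MIN_SEPARATION
    direction: str = "c_terminal_only"
    counting: str = "all_pairs"
    fit_offsets: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.disorder_threshold <= 1.0:
            raise ValueError("disorder_threshold must lie in [0, 1]")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.disorder_rule not in ("all_residues", "anchor_only"):
            raise ValueError(f"unknown disorder rule {self.disorder_rule!r}")

    def patterns(self):
        lx = (
            parse_pattern(self.lxvp_pattern, "LxVP_CN", 3)
            if self.lxvp_pattern
            else BUILTIN_PATTERNS["LxVP_CN"]
        )
        st = (
            parse_pattern(self.stxxp_pattern, "STxxP", 1)
            if self.stxxp_pattern
            else BUILTIN_PATTERNS["STxxP"]
        )
        return lx, st

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ScreenReport:
    pairings: pd.DataFrame
    summary: dict
    stage_counts: dict

    def write(self, out_dir: str) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.pairings.to_csv(out / "pairings.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=1)


def screen_proteins(records, tracks, config: RunConfig) -> ScreenReport:
    """Core screen over in-memory records and disorder tracks.

    ``tracks`` maps protein id -> DisorderTrack; a record without a track
    keeps no hits (everything is treated as ordered) and is logged.
    """
    lx_pat, st_pat = config.patterns()
    rows = []
    all_pairings = []
    counts = {"lxvp_hits": 0, "stxxp_hits": 0, "dropped_by_disorder": 0, "pairings": 0}
    for record in records:
        lx_hits = scan_sequence(record, lx_pat)
        st_hits = scan_sequence(record, st_pat)
        counts["lxvp_hits"] += len(lx_hits)
        counts["stxxp_hits"] += len(st_hits)
        track = tracks.get(record.id)
        if track is None:
            logger.warning("no disorder track for %s; all hits dropped", record.id)
            counts["dropped_by_disorder"] += len(lx_hits) + len(st_hits)
            continue
        lx_kept = filter_hits_by_disorder(
            lx_hits, track, config.disorder_threshold, config.disorder_rule
        )
        st_kept = filter_hits_by_disorder(
            st_hits, track, config.disorder_threshold, config.disorder_rule
        )
        counts["dropped_by_disorder"] += (len(lx_hits) - len(lx_kept)) + (
            len(st_hits) - len(st_kept)
        )
        pairings = pair_lxvp_stxxp(
            lx_kept, st_kept, config.min_separation, config.direction
        )
        counts["pairings"] += len(pairings)
        all_pairings.extend(pairings)
        for p in pairings:
            rows.append(
                {
                    "protein_id": p.protein_id,
                    "lxvp_start": p.lxvp_hit.start,
                    "lxvp_end": p.lxvp_hit.end,
                    "lxvp_anchor": p.lxvp_hit.anchor,
                    "lxvp_matched": p.lxvp_hit.matched,
                    "stxxp_anchor": p.stxxp_hit.anchor,
                    "stxxp_matched": p.stxxp_hit.matched,
                    "anchor_letter": p.anchor_letter,
                    "separation": p.separation,
                }
            )
    logger.info("screen stage counts: %s", counts)
    df = pd.DataFrame(
        rows,
        columns=[
            "protein_id", "lxvp_start", "lxvp_end", "lxvp_anchor", "lxvp_matched",
            "stxxp_anchor", "stxxp_matched", "anchor_letter", "separation",
        ],
    )
    summary = {
        "config": config.as_dict(),
        "stage_counts": counts,
        "cohort_all_pairs": summarize_cohort(all_pairings, "all_pairs").as_dict(),
        "cohort_nearest_lxvp": summarize_cohort(all_pairings, "nearest_lxvp").as_dict(),
    }
    return ScreenReport(pairings=df, summary=summary, stage_counts=counts)


def run_screen(config: RunConfig, out_dir: Optional[str] = None) -> ScreenReport:
    """Load FASTA + disorder TSVs per the config and run the screen."""
    if not config.fasta:
        raise ValueError("config.fasta is required")
    records = read_fasta(config.fasta)
    tracks = {}
    if config.disorder_dir:
        ddir = Path(config.disorder_dir)
        for record in records:
            path = ddir / f"{record.id}.iupred.tsv"
            if path.exists():
                tracks[record.id] = read_disorder_track(str(path), protein_id=record.id)
    report = screen_proteins(records, tracks, config)
    if out_dir:
        report.write(out_dir)
    return report


# ---------------------------------------------------------------------------
# Recovery harness
# ---------------------------------------------------------------------------

def recover_kinetics(timecourses, truth: dict, rel_tol: float = 0.05) -> pd.DataFrame:
    """Refit generated time courses and compare against the truth table.

    Sites planted at k = 0 are judged on the absolute rate (< ``rel_tol``
    in 1e-3 h^-1) since a relative error is undefined at zero.
    """
    rows = []
    true_rates = truth["k_dephos_1e-3_per_h"]
    for site, tcs in kinetics.group_by_site(timecourses).items():
        fit = kinetics.fit_site_rate(tcs)
        k_true = float(true_rates[site])
        if k_true > 0:
            rel = abs(fit.k_dephos - k_true) / k_true
            ok = rel < rel_tol
        else:
            rel = np.nan
            ok = abs(fit.k_dephos) < rel_tol
        rows.append(
            {
                "site_label": site,
                "parameter": "k_dephos_1e-3_per_h",
                "truth": k_true,
                "estimate": fit.k_dephos,
                "se": fit.k_se,
                "rel_error": rel,
                "converged": fit.converged,
                "pass": bool(ok),
            }
        )
    return pd.DataFrame(rows)


def recover_itc(experiment, truth: dict, rel_tol: float = 0.10) -> pd.DataFrame:
    fit = binding.fit_itc(experiment)
    rows = []
    for name, true_val, est, se in (
        ("n", truth["n"], fit.n, fit.n_se),
        ("K_D_M", truth["K_D_M"], fit.K_D, fit.K_D_se),
        ("dH_kcal_per_mol", truth["dH_kcal_per_mol"], fit.dH, fit.dH_se),
    ):
        rel = abs(est - true_val) / abs(true_val)
        rows.append(
            {
                "site_label": "itc",
                "parameter": name,
                "truth": true_val,
                "estimate": est,
                "se": se,
                "rel_error": rel,
                "converged": fit.converged,
                "pass": bool(rel < rel_tol),
            }
        )
    return pd.DataFrame(rows)


def recover_pnpp(substrate_M, rates, enzyme_total: float, truth: dict,
                 rel_tol: float = 0.10) -> pd.DataFrame:
    fit = binding.fit_michaelis_menten(substrate_M, rates, enzyme_total)
    rows = []
    for name, true_val, est, se in (
        ("Km_M", truth["Km_M"], fit.Km, fit.Km_se),
        ("Vmax_M_per_s", truth["Vmax_M_per_s"], fit.Vmax, fit.Vmax_se),
    ):
        rel = abs(est - true_val) / abs(true_val)
        rows.append(
            {
                "site_label": "pnpp",
                "parameter": name,
                "truth": true_val,
                "estimate": est,
                "se": se,
                "rel_error": rel,
                "converged": fit.converged,
                "pass": bool(rel < rel_tol),
            }
        )
    return pd.DataFrame(rows)


def run_recover(dataset_dir: str, rel_tol: float = 0.10) -> pd.DataFrame:
    """Recover every dataset type found in a generated-bundle directory.

    Expects the layout written by the ``simulate`` subcommand:
    ``timecourses.csv`` + ``timecourses.truth.json``, ``itc.csv`` +
    ``itc.truth.json``, ``pnpp.csv`` + ``pnpp.truth.json`` (any subset).
    """
    d = Path(dataset_dir)
    frames = []
    tc_path = d / "timecourses.csv"
    if tc_path.exists():
        truth = _load_truth(d / "timecourses.truth.json")
        frames.append(recover_kinetics(kinetics.read_timecourses(str(tc_path)), truth, rel_tol))
    itc_path = d / "itc.csv"
    if itc_path.exists():
        truth = _load_truth(d / "itc.truth.json")
        frames.append(recover_itc(binding.read_itc_csv(str(itc_path)), truth, rel_tol))
    pnpp_path = d / "pnpp.csv"
    if pnpp_path.exists():
        truth = _load_truth(d / "pnpp.truth.json")
        S, v = binding.read_pnpp_csv(str(pnpp_path))
        frames.append(
            recover_pnpp(S, v, truth.get("enzyme_total_M", 0.5e-6), truth, rel_tol)
        )
    if not frames:
        raise FileNotFoundError(f"no recoverable datasets found in {dataset_dir}")
    return pd.concat(frames, ignore_index=True)


def _load_truth(path: Path) -> dict:
    if not path.exists():
        raise FileNotFoundError(f"missing truth table {path}")
    try:
        with open(path) as fh:
            return json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupted truth table {path}: {exc}") from exc
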