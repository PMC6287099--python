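"""Parameter-recovery harness: did the per-breed TAG scan find the
planted sweep?

Runs breed-vs-pooled-others Fst plus XP-EHH on a simulated cohort's
in-memory tables and applies the TAG rule (ZFst >= 4 AND top-1% window
XP-EHH), reporting whether the window containing the true selected site
was flagged.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import haplotype_ehh, sweep_scan
from .simdata import SimCohort


def tag_scan_frame(
    cohort: SimCohort,
    focal: str = "dairy",
    window: int = 100_000,
    fst_estimator: str = "hudson",
) -> pd.DataFrame:
    """Per-window chrom/start/end/fst/zfst/xpehh for one focal breed."""
    windows = sweep_scan.tile_windows(cohort.contig_lengths, window)
    groups = cohort.groups
    breeds = [b for b in ("dairy", "cashmere", "meat") if b in groups.labels()]
    others = [s for b in breeds if b != focal for s in groups[b]]
    fst = sweep_scan.fst_windows(cohort.table, groups[focal], others, windows, fst_estimator)
    df = pd.DataFrame(windows, columns=["chrom", "start", "end"])
    df["fst"] = fst
    df["zfst"] = sweep_scan.z_transform(fst)
    chrom = cohort.truth.config.chrom
    panel_f, panel_r = haplotype_ehh.paired_panels(
        cohort.table, groups[focal], others, focal, f"not_{focal}", chrom
    )
    scores, _ = haplotype_ehh.xpehh_scan(panel_f, panel_r, chrom)
    df["xpehh"] = haplotype_ehh.window_xpehh(scores, windows)
    return df


def sweep_recovery(cohort: SimCohort, window: int = 100_000) -> dict:
    """TAG calls for the swept breed plus whether the true sweep window
    was flagged; also reports the flagged-window fraction (false-positive
    load on neutral cohorts)."""
    focal = cohort.truth.sweep_population or "dairy"
    df = tag_scan_frame(cohort, focal, window)
    calls, _ = sweep_scan.classify_tags(df, cohort.genes)
    n_windows = len(df)
    out = {
        "n_windows": n_windows,
        "n_flagged": len(calls),
        "flagged_fraction": len(calls) / n_windows if n_windows else 0.0,
    }
    sel = cohort.truth.selected_pos
    if sel is not None:
        hit = any(c.start <= sel < c.end for c in calls)
        i = int(np.flatnonzero((df.start <= sel) & (sel < df.end))[0])
        out.update(
            hit=bool(hit),
            sweep_window_zfst=float(df.zfst[i]),
            sweep_window_xpehh=float(df.xpehh[i]),
        )
    return out
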