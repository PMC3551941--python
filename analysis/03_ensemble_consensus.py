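#!/usr/bin/env python
"""Combine the projections into TSS-weighted consensus maps; compute
richness, per-cell species turnover, per-species range change, and the
cellwise two-way ANOVA partition of projection variance into modelling
methods vs climate scenarios (the uncertainty layer, turned into the
prioritization cost c_i = 1 + uncertainty proportion).
"""

from pathlib import Path

from climprior import pipeline as pl

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    state = pl.load_simulated(OUTDIR)
    pl.load_enm(state, OUTDIR)
    pl.stage_ensemble(state, OUTDIR)
    s = state.range_summary
    print(f"range change (consensus, current vs pooled future):")
    print(f"  mean contraction {s['mean_contraction_pct']:.1f}% "
          f"(SD {s['sd_contraction_pct']:.1f}, max {s['max_contraction_pct']:.1f})")
    print(f"  regionally extinct: {s['pct_extinct']:.1f}% of "
          f"{s['n_baseline_present']} species")
    tm = state.turnover_map
    print(f"turnover range: {tm.turnover.min():.2f} - {tm.turnover.max():.2f}")
    um = state.uncertainty
    tot = um.ss_total.sum()
    print(f"variance partition: methods {100 * um.ss_method.sum() / tot:.1f}%, "
          f"scenarios {100 * um.ss_gcm.sum() / tot:.1f}%, "
          f"interaction {100 * um.ss_residual.sum() / tot:.1f}%")


if __name__ == "__main__":
    main()
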