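#!/usr/bin/env python
"""Estimate apparent RFC arrival/dissociation rates from single-molecule traces.

Simulates two-color traces (labeled RFC injected 10 s into recording at the
single standard concentration), extracts arrival, FRET, and loss events by
two-state thresholding, and estimates exponential rates from the pooled
dwells with bootstrap confidence intervals, plus the proximity-ratio FRET
efficiency over the bound window.
"""

import argparse

from ptckin.io import write_json
from ptckin.simulate import GeneratorConfig, gen_fret_trace
from ptckin.smfret import DwellSet, estimate_rates


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results")
    ap.add_argument("--n-traces", type=int, default=300)
    args = ap.parse_args()

    cfg = GeneratorConfig(seed=args.seed, snr=5.0)
    rng = cfg.rng()
    traces = [gen_fret_trace(cfg, rng, trace_id=f"tr-{i:04d}")
              for i in range(args.n_traces)]
    ds = DwellSet.from_traces(traces)
    ds = estimate_rates(ds, seed=cfg.seed + 5)

    out = {"n_traces": args.n_traces, "n_arrivals": len(ds.arrival_waits),
           "k_arrival_app_s": ds.k_arrival_app,
           "k_dis_tRNA_app_s": ds.k_dis_tRNA_app,
           "k_dis_eRF1_app_s": ds.k_dis_eRF1_app,
           "E": ds.E, "ci": ds.ci,
           "truth": {"k_arrival_s": cfg.k_arrival_s,
                     "k_dis_tRNA_s": cfg.k_dis_tRNA_s,
                     "k_dis_eRF1_s": cfg.k_dis_eRF1_s, "E": cfg.E_true}}
    write_json(out, f"{args.outdir}/smfret.json")
    for name in ("k_arrival_app", "k_dis_tRNA_app", "k_dis_eRF1_app"):
        lo, hi = ds.ci[name]
        print(f"{name}: {getattr(ds, name):.3f} /s  (95% CI {lo:.3f}-{hi:.3f})")
    print(f"FRET efficiency E = {ds.E:.3f} "
          f"({len(ds.arrival_waits)} arrivals from {args.n_traces} traces)")


if __name__ == "__main__":
    main()
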