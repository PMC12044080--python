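#!/usr/bin/env python
"""Stage 6 (optional) — Manhattan plot of the association scan.

Requires matplotlib (install with the ``plot`` extra); all other stages are
plot-free.
"""

import argparse
from pathlib import Path

from heartqtl import io
from heartqtl.pipeline import AnalysisConfig


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--config", default="analysis/config.yaml")
    parser.add_argument("--phenotype", default="hr28")
    args = parser.parse_args()
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        raise SystemExit(
            "matplotlib is not installed; install the 'plot' extra to make figures"
        )

    cfg = AnalysisConfig.from_yaml(args.config)
    out = Path(cfg.out_dir)
    scan = io.read_scan(out / "scan.tsv")
    thresholds = io.read_thresholds(out / "fdr_thresholds.json")
    sub = scan[scan["phenotype"] == args.phenotype]

    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    for i, (chrom, grp) in enumerate(sub.groupby("chrom", sort=True)):
        mid = (grp["start"] + grp["end"]) / 2 + offset
        ax.scatter(mid, grp["neg_log10_p"], s=4, color=f"C{i % 2}", label=chrom)
        offset += grp["end"].max()
    thr = thresholds[args.phenotype].thresholds[cfg.fdr_level]
    ax.axhline(thr, color="red", linestyle="--", linewidth=0.8,
               label=f"{int(cfg.fdr_level * 100)}% FDR")
    ax.set_xlabel("genome position")
    ax.set_ylabel("-log10 p")
    ax.set_title(f"Association scan, {args.phenotype}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / f"manhattan_{args.phenotype}.png", dpi=150)
    print(f"wrote {out}/manhattan_{args.phenotype}.png")


if __name__ == "__main__":
    main()
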