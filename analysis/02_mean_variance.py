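"""Fit per-gene mean-variance lines on the simulated stimulation panel.

Reads results/data/linear_family, median-scales it (background genes
carry the depth), fits the robust line sigma^2 = alpha mu + alpha0 per
gene, and writes results/mean_variance_fits.tsv.  Prints the
high-confidence tally and the recovered slope of the responsive genes
(generated at alpha = 3).
"""

from pathlib import Path

from burstlin.dataio import median_scale, read_counts
from burstlin.pipelines import mean_variance_study

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = ROOT / "data" / "linear_family"
    ds = read_counts(data / "counts.mtx", data / "meta.tsv")
    nds = median_scale(ds)
    fits, frame = mean_variance_study(nds)
    responsive = frame[frame["gene_id"].str.startswith("g")]
    responsive.to_csv(ROOT / "mean_variance_fits.tsv", sep="\t", index=False)
    high = responsive[responsive["confidence_class"] == "high_confidence"]
    print(f"{len(high)}/{len(responsive)} responsive genes high-confidence")
    print(f"median slope {high['alpha'].median():.2f} (generated at 3.0; median\n"
          "scaling compresses slopes slightly when responsive genes carry\n"
          "a visible share of depth - see docs/methods.md)")
    print(f"median R^2 {high['r2'].median():.3f}")


if __name__ == "__main__":
    main()
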