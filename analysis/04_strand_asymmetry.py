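"""Strand asymmetry of contextual influence.

Simulates two genomes annotated on a single strand: one whose T->C rate has
a 5'-A enhancer with no counterpart on the complementary strand (a
transcription-coupled-repair-like asymmetry), and one where the enhancer is
mirrored (3'-T on A->G), i.e. a strand-symmetric process. For each, the
per-direction variance posteriors of every strand-complementary pair are
compared by the 97.5-vs-2.5 percentile criterion.

    python analysis/04_strand_asymmetry.py --seed 1
"""

import argparse
from pathlib import Path

import pandas as pd

from mutvar import context as ctx
from mutvar import filters, genomic_io as gio, synthetic
from mutvar._util import STRAND_PAIRS
from mutvar.synthetic import ContextRateModel, GenomeSimParams, NeighborEffect


def analyse(label: str, effects, seed: int, draws: int) -> list[dict]:
    rm = ContextRateModel(neighbor_effects=tuple(effects))
    genome, mask, variants, _ = synthetic.simulate_genome(GenomeSimParams(
        length=2_000_000, rate_model=rm, seed=seed))
    qualified = filters.qualify_context_variants(variants, mask, genome=genome)
    table = ctx.tally_cells(qualified, genome, mask, 3)
    rows = []
    for d_a, d_b in STRAND_PAIRS:
        pa = ctx.variance_by_direction(table, d_a, n_draws=draws, seed=seed)
        pb = ctx.variance_by_direction(table, d_b, n_draws=draws, seed=seed)
        res = ctx.strand_asymmetry(pa, pb)
        rows.append({"regions": label,
                     "pair": f"{d_a[0]}>{d_a[1]} / {d_b[0]}>{d_b[1]}",
                     "asymmetric": res.asymmetric,
                     "a_lo": res.percentiles["a"][0],
                     "a_hi": res.percentiles["a"][1],
                     "b_lo": res.percentiles["b"][0],
                     "b_hi": res.percentiles["b"][1]})
    return rows


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--draws", type=int, default=4000)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    asym = [NeighborEffect(-1, "A", 5.0, ("T", "C"))]
    sym = asym + [NeighborEffect(+1, "T", 5.0, ("A", "G"))]
    rows = (analyse("asymmetric-process", asym, args.seed, args.draws)
            + analyse("symmetric-process", sym, args.seed + 1, args.draws))
    df = pd.DataFrame(rows)
    gio.write_table(df, args.outdir / "strand_asymmetry.tsv")

    for label in ("asymmetric-process", "symmetric-process"):
        sub = df[df["regions"] == label]
        called = sub[sub["asymmetric"]]["pair"].tolist()
        print(f"{label}: {len(called)} of {len(sub)} pairs called asymmetric"
              + (f" ({', '.join(called)})" if called else ""))
    print("only the un-mirrored T>C enhancer should separate its pair's "
          "posteriors; mirrored effects cancel on oriented data")


if __name__ == "__main__":
    main()
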