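"""Generate the synthetic drug-screen panel the downstream analyses use.

Emulates a small cell-line screen: 52 solid-tumor training lines plus 6
resistant blood-derived lines, an independent 37-line blind cohort, 2000
genes with five planted causal genes (one dominant driver). Full data go to
scratch/data/ (large); a small cohort summary goes to results/.
"""

from pathlib import Path

import pandas as pd

from drugsig import GeneratorConfig, generate_dataset
from drugsig.io import write_expression_matrix, write_gene_sets, write_network, write_sensitivity_table
from drugsig.simulate import generate_gene_sets_fixture, generate_network_fixture

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(GeneratorConfig(seed=SEED))

    write_expression_matrix(ds.expression, DATA / "expression_train.tsv")
    write_sensitivity_table(ds.sensitivity, DATA / "sensitivity_train.tsv")
    write_expression_matrix(ds.blind_expression, DATA / "expression_blind.tsv")
    write_sensitivity_table(ds.blind_sensitivity, DATA / "sensitivity_blind.tsv")
    genes, causal = ds.expression.gene_ids, ds.truth["causal_genes"]
    write_gene_sets(generate_gene_sets_fixture(genes, causal, seed=SEED), DATA / "gene_sets.gmt")
    write_network(generate_network_fixture(genes, causal, seed=SEED), DATA / "network.sif")
    pd.DataFrame(
        {
            "gene": causal,
            "beta": [ds.truth["effect_sizes"][g] for g in causal],
            "dominant": [g == ds.truth["dominant_gene"] for g in causal],
        }
    ).to_csv(DATA / "truth.tsv", sep="\t", index=False, lineterminator="\n")

    tab = ds.sensitivity.table
    summary = (
        tab.groupby("lineage")
        .agg(n=("ic50_molar", "size"),
             ic50_min_molar=("ic50_molar", "min"),
             ic50_max_molar=("ic50_molar", "max"),
             neglog10_mean=("neglog10", "mean"))
    )
    summary.to_csv(RESULTS / "01_panel_summary.tsv", sep="\t", lineterminator="\n",
                   float_format="%.4g")

    print(f"wrote panel to {DATA} (seed {SEED})")
    print(f"training cohort: {len(tab)} lines "
          f"({(tab.lineage == 'blood').sum()} blood, to be excluded), "
          f"blind cohort: {len(ds.blind_sensitivity.table)} lines")
    print(f"dominant driver: {ds.truth['dominant_gene']} (beta 1.5), "
          f"{len(causal) - 1} weaker causal genes (beta 0.4)")
    print(summary.to_string(float_format=lambda v: f"{v:.3g}"))


if __name__ == "__main__":
    main()
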