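"""Descriptive follow-up analyses of the derived signature.

Co-clusters the most sensitivity-correlated genes across the most extreme
cell lines, tests the top correlates for differential expression between
predicted-sensitive and predicted-resistant blind lines (Wilcoxon), overlaps
the training-correlation gene list with the blind predicted-sensitivity
correlation list, and runs gene-set enrichment of the top correlates.
"""

from pathlib import Path

import pandas as pd

from drugsig import (
    coclustering_agreement,
    enrichment_test,
    hierarchical_cluster,
    list_overlap,
    pearson_screen,
    predict_ic50,
    select_top_correlates,
    wilcoxon_rank_sum,
)
from drugsig.io import align_samples, exclude_lineage, read_expression_matrix, read_gene_sets, read_sensitivity_table
from drugsig.select import load_signature_model

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    expr = read_expression_matrix(DATA / "expression_train.tsv")
    sens = exclude_lineage(read_sensitivity_table(DATA / "sensitivity_train.tsv"), "blood")
    expr, sens = align_samples(expr, sens)
    y = sens.neglog10

    corr = pearson_screen(expr, y.to_numpy())
    top20 = select_top_correlates(corr, 10, 10)

    # co-clustering: top-5 most sensitive and top-5 most resistant lines
    extremes = list(y.sort_values().index[:5]) + list(y.sort_values().index[-5:])
    sub = expr.values.loc[top20, extremes]
    clusters = hierarchical_cluster(sub, axis="samples").labels_at(2)
    truth = pd.Series(["resistant"] * 5 + ["sensitive"] * 5, index=extremes)
    agree = coclustering_agreement(clusters, truth)

    # Wilcoxon differential expression of the top correlates between
    # predicted-sensitive and predicted-resistant blind lines
    blind_expr = read_expression_matrix(DATA / "expression_blind.tsv")
    model = load_signature_model(ROOT / "scratch" / "model.json")
    pred = predict_ic50(model, blind_expr)
    sens_lines = pred.table.index[pred.table["call"] == "sensitive"]
    res_lines = pred.table.index[pred.table["call"] == "resistant"]
    rows = []
    for gene in top20:
        a = blind_expr.values.loc[gene, sens_lines].to_numpy()
        b = blind_expr.values.loc[gene, res_lines].to_numpy()
        w, p = wilcoxon_rank_sum(a, b)
        rows.append({"gene": gene, "rank_sum": w, "p": p,
                     "mean_diff": float(a.mean() - b.mean())})
    wilcoxon_table = pd.DataFrame(rows).set_index("gene")
    wilcoxon_table.to_csv(RESULTS / "04_wilcoxon_top20.tsv", sep="\t", lineterminator="\n")

    # overlap of top-100 correlate lists: actual training sensitivity vs
    # predicted blind sensitivity
    top200_train = select_top_correlates(corr, 100, 100)
    blind_corr = pearson_screen(blind_expr, pred.table["pred_neglog10"].to_numpy())
    top200_blind = select_top_correlates(blind_corr, 100, 100)
    inter, fa, fb = list_overlap(top200_train, top200_blind)

    # enrichment of the top correlates against the gene-set fixture
    sets = read_gene_sets(DATA / "gene_sets.gmt")
    enr = enrichment_test(top200_train, sets, expr.gene_ids, fdr_threshold=0.05)
    enr.table.sort_values("p").to_csv(RESULTS / "04_enrichment.tsv", sep="\t",
                                      lineterminator="\n")

    summary = pd.DataFrame(
        {
            "quantity": [
                "coclustering_agreement_extreme10",
                "top20_wilcoxon_significant",
                "top_correlate_overlap_fraction",
                "enriched_sets_fdr_0.05",
            ],
            "value": [
                agree,
                int((wilcoxon_table["p"] <= 0.05).sum()),
                round(fa, 4),
                len(enr.significant_sets),
            ],
        }
    )
    summary.to_csv(RESULTS / "04_summary.tsv", sep="\t", index=False, lineterminator="\n")

    print(f"co-clustering of 10 extreme lines on top-20 correlates: "
          f"{agree:.2f} agreement with the true grouping")
    print(f"{int((wilcoxon_table['p'] <= 0.05).sum())}/20 top correlates "
          f"differentially expressed (Wilcoxon p <= 0.05) between predicted groups")
    print(f"top-100/-100 correlate lists (train vs blind-predicted) share "
          f"{len(inter)} genes ({100 * fa:.1f}% of each)")
    print(f"{len(enr.significant_sets)} gene set(s) enriched at FDR <= 0.05: "
          f"{', '.join(enr.significant_sets) or '-'}")


if __name__ == "__main__":
    main()
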