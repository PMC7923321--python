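"""Derive the sensitivity signature from the simulated training cohort.

Runs the full funnel (correlation screen -> pathway/network filters ->
RReliefF -> Boruta -> backward elimination) on the panel written by
01_simulate.py. Small audit tables go to results/derive/; the full
correlation screen and the serialized model go to scratch/.
"""

from pathlib import Path

import pandas as pd

from drugsig import PipelineConfig, derive_signature
from drugsig.io import read_expression_matrix, read_gene_sets, read_network, read_sensitivity_table
from drugsig.pipeline import write_derivation_artifacts
from drugsig.select import save_signature_model

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results" / "derive"
SEED = 1


def main() -> None:
    expr = read_expression_matrix(DATA / "expression_train.tsv")
    sens = read_sensitivity_table(DATA / "sensitivity_train.tsv")
    gene_sets = read_gene_sets(DATA / "gene_sets.gmt")
    network = read_network(DATA / "network.sif")
    truth = pd.read_csv(DATA / "truth.tsv", sep="\t")
    dominant = truth.loc[truth["dominant"], "gene"].iloc[0]

    res = derive_signature(
        expr, sens, PipelineConfig(seed=SEED),
        gene_sets=gene_sets, network=network, target_genes=[dominant],
    )

    audit = ROOT / "scratch" / "derive_audit"
    paths = write_derivation_artifacts(res, audit)
    RESULTS.mkdir(parents=True, exist_ok=True)
    for small in ("signature", "trace", "counts", "boruta"):
        (RESULTS / paths[small].name).write_bytes(paths[small].read_bytes())
    save_signature_model(res.model, ROOT / "scratch" / "model.json")

    print("funnel:", " -> ".join(f"{k}={v}" for k, v in res.stage_counts.items()))
    print(f"signature ({len(res.model.signature)} genes):", ", ".join(res.model.signature))
    print("normalized importances:")
    print(res.model.importances.round(3).to_string())
    in_sig = dominant in res.model.signature
    print(f"dominant driver {dominant} in signature: {in_sig}; "
          f"importance share {res.model.importances.get(dominant, 0.0):.2f}")


if __name__ == "__main__":
    main()
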