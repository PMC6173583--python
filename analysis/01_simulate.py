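#!/usr/bin/env python
"""Generate the synthetic study used by all downstream analyses.

Writes the reference cohort (71 healthy samples, five planted coexpression
modules among 1000 genes), five injured/sham test studies, the heavy-tailed
interactome with a densely wired curated neighborhood, GO-like annotations,
complexes and cell-type profiles, the literature-curated gene table with
ortholog tables, and the ground-truth record — all under scratch/synthetic/
(bulky regenerable data; every downstream script reads from there).
"""

from pathlib import Path

from cordnet import io
from cordnet.simulate import (
    SimulationConfig,
    generate_annotations,
    generate_curated_set,
    generate_interactome,
    generate_ortholog_tables,
    generate_reference_expression,
    generate_test_studies,
)

OUT = Path(__file__).resolve().parent.parent / "scratch" / "synthetic"
SEED = 1

# planted density 0.05 keeps planted degrees on the scale of the background
# degree distribution (see docs/methods.md)
CONFIG = SimulationConfig(rng_seed=SEED, planted_subgraph_density=0.05)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ref, truth = generate_reference_expression(CONFIG)
    io.write_expression(ref, OUT / "reference_expr.tsv", OUT / "reference_meta.tsv")
    for i, study in enumerate(generate_test_studies(CONFIG, truth)):
        io.write_expression(
            study, OUT / f"study{i}_expr.tsv", OUT / f"study{i}_meta.tsv"
        )
    net = generate_interactome(CONFIG, truth)
    io.write_edge_list(net, OUT / "interactome.tsv")
    ann = generate_annotations(CONFIG, truth)
    io.write_annotations(ann.go, OUT / "annotations.gmt")
    io.write_gmt(ann.complexes, OUT / "complexes.gmt")
    ann.cell_profiles.profiles.to_csv(OUT / "cell_profiles.tsv", sep="\t")
    _, table = generate_curated_set(CONFIG, truth)
    io.write_curated_table(table, OUT / "curated.tsv")
    for t in generate_ortholog_tables(CONFIG, truth):
        io.write_ortholog_table(t, OUT / f"orthologs_{t.database_name}.tsv")
    io.write_truth(truth.as_dict(), OUT / "truth.json")
    print(f"reference: {ref.n_genes} genes x {ref.n_samples} samples")
    print(f"interactome: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges")
    print(f"curated set: {len(truth.curated_genes)} genes "
          f"({sum(truth.curated_is_tp)} true positives)")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
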