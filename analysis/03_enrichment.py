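"""Fisher's-exact GO/pathway over-representation of the up- and
down-regulated mRNA lists against the annotated-array universe."""

from _common import load_dataset, results_dir
from lncnet.enrichment import fisher_enrichment, read_gene_list, top_terms, write_enrichment
from lncnet.pipeline import default_universe

if __name__ == "__main__":
    _, annotation, gene_sets = load_dataset()
    out = results_dir()
    universe = default_universe(annotation, gene_sets)
    print(f"enrichment universe: {len(universe)} annotated gene symbols, {len(gene_sets)} terms")
    for direction in ("up", "down"):
        probes = read_gene_list(out / f"{direction}_mrna.txt")
        genes = annotation.symbols_for(probes)
        res = fisher_enrichment(genes, gene_sets, universe)
        write_enrichment(res, out / f"enrichment_{direction}.tsv")
        best = top_terms(res, "biological_process", 1)
        if len(best):
            print(f"{direction}-regulated ({len(genes)} genes): top biological_process "
                  f"term {best.at[0, 'term_id']} p = {best.at[0, 'p_value']:.3g} "
                  f"(k/K = {best.at[0, 'k']}/{best.at[0, 'K']})")
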