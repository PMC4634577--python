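"""Function classification by pose comparison, with the MCC grid search.

Generates 10 isofunctional site families (one planted in two superfamilies
as a synthetic NISE case), compares all sites pairwise, and searches the
(cu_RMSD_N2, cu_S_GO) cutoff grid for the MCC-maximizing classifier in
non-homologs-only (DIFF_SF) mode.
"""

from catsim import Agreement, EvaluationConfig, Mode, grid_search
from catsim.pipeline import all_vs_all, sgo_matrix
from catsim.synthetic import SyntheticConfig, make_ontology, make_sites

cfg = SyntheticConfig(seed=0, n_families=10, sites_per_family=5,
                      noise_sigma=0.1)
onto, annos = make_ontology(cfg)
sites, _ = make_sites(cfg, (onto, annos))
print(f"{len(sites)} sites in {cfg.n_families} families, "
      f"noise sigma {cfg.noise_sigma} A")

sgo = sgo_matrix(sites, onto, ["BP", "MF"])
comparisons = all_vs_all(sites, rmsd_cutoff=3.0, sgo=sgo,
                         skip_budget_exceeded=True)

result = grid_search(
    comparisons, EvaluationConfig(mode=Mode.DIFF_SF, agreement=Agreement.GO))
c = result.counts
print(f"optimal cutoffs: cu_RMSD_N2 = {result.cu_rmsd:.2f} A, "
      f"cu_S_GO = {result.cu_sgo:.2f}")
print(f"confusion counts: TP={c.tp} FP={c.fp} TN={c.tn} FN={c.fn}")
print(f"maximal MCC = {result.mcc:.2f}")

# Each query's most similar non-homologous site is its best hit; a best
# hit below cu_RMSD_N2 predicts a function transfer, judged correct when
# the GO term-set similarity of query and hit reaches cu_S_GO. At 0.1 A
# noise the planted family structure is cleanly separable, so the grid
# search finds a cutoff pair with MCC close to 1.
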