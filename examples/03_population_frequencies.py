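"""Per-population CLL-SLS frequencies and the Kruskal-Wallis comparison.

Simulates three donors, each with a naive, a memory and a cord-blood-like
(TdT-off) population, then tabulates per-donor standard/satellite
frequencies by population and tests whether the per-donor standard
frequencies differ across populations (Kruskal-Wallis with Dunn post-hoc
pairs, Holm-adjusted).
"""

from cllsls import assign_all, load_catalog, summarize, summaries_to_frame, toy_catalog_path
from cllsls.simulate import default_config, simulate
from cllsls.stats import kruskal_wallis

catalog = load_catalog(toy_catalog_path())
rearrangements, truth = simulate(default_config(seed=7), catalog)
assignments = assign_all(rearrangements, catalog)
frame = summaries_to_frame(summarize(assignments, rearrangements))

print(frame.to_string(index=False, float_format=lambda x: f"{x:.4f}"))

populations = sorted(frame.population.unique())
groups = [frame.loc[frame.population == p, "freq_standard"].tolist() for p in populations]
kw = kruskal_wallis(groups, labels=populations)
print(f"\nKruskal-Wallis on freq_standard across populations: H={kw.statistic:.3f} p={kw.pvalue:.3f}")
print(kw.posthoc.to_string(index=False, float_format=lambda x: f"{x:.3f}"))

print(
    "\nPlants enter every population at the same per-sequence rate, so NAIVE and MEM\n"
    "frequencies agree. The TdT-off CB population collapses to far fewer unique\n"
    "background clonotypes while plants stay distinct, so its per-clonotype\n"
    "frequencies run higher — the same denominator effect that makes low-diversity\n"
    "repertoires look enriched. Planting at population-specific rates makes real\n"
    "enrichment detectable by the same test."
)
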