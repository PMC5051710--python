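"""Simulate a volunteer-count dataset from the open N-mixture model.

Builds a small study-like scenario (30 road-crossing sites over four
decades, decade-specific growth and detection), draws latent abundances
and observed seasonal totals, and prints the dataset summary.  The mean
series length and the count range mirror the design of the national
toad-patrol datasets.
"""

from opennmix import Scenario, dataset_summary, simulate_dataset

scenario = Scenario(n_sites=30, seed=42)
dataset, truth = simulate_dataset(scenario)

summary = dataset_summary(dataset)
print(f"sites simulated:      {summary.n_sites}")
print(f"mean series length:   {summary.mean_series_length} observed years")
print(f"year span:            {summary.year_range[0]}-{summary.year_range[1]}")
print(f"count quartiles:      {summary.count_quantiles}")
print()
print("true growth rates by decade (lambda < 1 means decline):")
for key, lam in truth.lambda_table.items():
    print(f"  {key}: {lam:.3f}")

one = dataset.series[0]
print(f"\nexample series {one.site_id}: years {one.first_year}-{one.last_year}")
print(f"  counts: {one.counts}")
first, latent = truth.latent(one.site_id)
print(f"  latent abundance that produced them: {tuple(int(n) for n in latent)}")
print("(counts sit below the latent states because detection is imperfect)")
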