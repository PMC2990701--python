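"""Generate a synthetic country and inspect its reporting ground truth.

The generator draws 152 municipalities in 7 environmental regions and 5
years of weekly snakebite counts; the most deprived municipalities
report only a fraction of their true cases.
"""

from snakemap import SyntheticConfig, simulate_cases, simulate_municipalities

cfg = SyntheticConfig(seed=1)
mun = simulate_municipalities(cfg)
cases, truth = simulate_cases(mun, cfg)

print(f"municipalities: {len(mun)}, total population: {mun['population'].sum():,}")
print(f"true cases over {cfg.years} years: {cases['true_cases'].sum():,}")
print(f"reported cases: {cases['cases'].sum():,} (deaths: {cases['deaths'].sum()})")
n_under = truth.table["underreporter_flag"].sum()
print(f"true underreporters (reporting probability < {cfg.underreporter_cutoff}): {n_under}")
# The gap between true and reported counts is concentrated in those
# municipalities - the bias the analysis pipeline is designed to expose.
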