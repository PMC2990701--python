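"""National descriptive statistics and smoothed seasonal curves."""

from snakemap import (
    RegionAssignment,
    SyntheticConfig,
    incidence_summary,
    regional_incidence,
    seasonal_curves,
    simulate_cases,
    simulate_municipalities,
)

cfg = SyntheticConfig(seed=1)
mun = simulate_municipalities(cfg)
cases, _ = simulate_cases(mun, cfg)
assignment = RegionAssignment(
    table=mun[["municipality_id", "sim_region"]].rename(columns={"sim_region": "region"})
)

s = incidence_summary(cases, mun, years=cfg.years)
r = s.rounded()
print(f"{s.total_cases:,} reported cases among {s.population:,} inhabitants")
print(f"5-year incidence: {r['incidence_per_100k']} per 100,000 "
      f"({r['annual_incidence_per_100k']} per year)")
print(f"mortality: {r['mortality_per_100k']} per 100,000 in {cfg.years} years; "
      f"case fatality rate: {r['case_fatality_pct']}%")

print("\nper-region 5-year incidence per 100,000:")
print(regional_incidence(cases, mun, assignment)
      .round(1).to_string(index=False))

grouping = {r_: ("East" if r_.startswith("East") else "West")
            for r_ in assignment.table["region"].unique()}
curves = seasonal_curves(cases, assignment, grouping, window=5)
for region, grp in curves.groupby("region"):
    peak = grp.loc[grp["smoothed"].idxmax(), "week"]
    trough = grp.loc[grp["smoothed"].idxmin(), "week"]
    ratio = grp["smoothed"].max() / max(grp["smoothed"].min(), 1e-9)
    print(f"{region}: seasonal peak week {peak}, trough week {trough}, "
          f"peak/trough ratio {ratio:.1f} (5-week sliding mean)")
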