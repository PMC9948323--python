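"""Generate the scenario's rainfall grid and survey tables.

Writes rain_grid.csv (long format), sites.csv and respondents.csv under
results/analysis/ and prints the headline sample characteristics.
"""

from scenario import RESULTS, make_config

from rainmob import gen_rain_grid, gen_survey


def main() -> None:
    cfg = make_config()
    RESULTS.mkdir(parents=True, exist_ok=True)
    grid = gen_rain_grid(cfg.seed, **cfg.grid)
    sites, respondents = gen_survey(cfg.dgp_spec(), grid)

    grid.to_csv(RESULTS / "rain_grid.csv")
    sites.to_csv(RESULTS / "sites.csv", index=False)
    respondents.to_csv(RESULTS / "respondents.csv", index=False)

    print(f"grid: {grid.values.shape[0]}x{grid.values.shape[1]} cells, "
          f"{grid.n_days} days ({grid.start_date} .. {grid.end_date})")
    print(f"sites: {len(sites)} in {sites['country'].nunique()} countries; "
          f"urban share {sites['urban'].mean():.3f}")
    print(f"respondents: {len(respondents)}; "
          f"women {(respondents['gender'] == 'woman').mean():.3f}; "
          f"married {respondents['married'].mean():.3f}; "
          f"literate {respondents['literate'].mean():.3f}")


if __name__ == "__main__":
    main()
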