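"""One-call pipeline run plus the EM vs complete-case comparison.

`run` executes simulate -> degrade -> impute -> fit for every requested
pollutant and writes panel, imputed panel, tidy estimates and a manifest
with checksums; `compare_imputation` contrasts EM imputation with the
complete-case sensitivity analysis on the same degraded panel.
"""

from airdlm import RunConfig, SimConfig, run, compare_imputation

cfg = RunConfig(
    mode="simulate",
    sim=SimConfig(n_days=1200, seed=6),  # null effects: true RR = 1 throughout
    pollutants=("pm10", "no2"),
    variants=("single",),
    outdir="scratch/example_run",
    seed=6,
)
manifest = run(cfg)
print("stages:", {k: v.get("seconds") for k, v in manifest["stages"].items()})
print("outputs:", sorted(manifest["outputs"]))
print("PM10 model dispersion:",
      round(manifest["stages"]["fit"]["models"]["pm10"]["dispersion"], 2),
      "(quasi-Poisson phi; >1 means overdispersed counts)")

report = compare_imputation(cfg)
print(f"\ncomplete case retains {report.attrs['retained_fraction']:.0%} of days")
print(report[["pollutant", "mode", "rr", "se", "covers_truth"]].to_string(index=False))
print("no true effects here, so both modes should cover RR = 1; "
      "complete case pays for its dropped days with larger SEs")
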