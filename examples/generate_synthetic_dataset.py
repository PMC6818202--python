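"""Generate a FAERS-like dataset with known ground truth.

Writes dollar-delimited demo/drug/reac files (the format the ingest stage
reads) plus a manifest recording, for every emitted report version, which
unique case it belongs to and the planted exposure/event/condition truth.
The planted per-drug `true_ror` is exactly the report-level quantity the
pipeline's ROR estimates.
"""

from pvror.synthetic import DrugSpec, GeneratorConfig, generate

config = GeneratorConfig(
    n_cases=1000,
    drug_catalog={
        "DAPTOMYCIN": DrugSpec(p_exposure=0.05, true_ror=18.0, synonyms=("CUBICIN",)),
        "MEROPENEM": DrugSpec(p_exposure=0.05, true_ror=3.0, synonyms=("MERREM",)),
        "CEFACLOR": DrugSpec(p_exposure=0.05, true_ror=1.0, synonyms=("CECLOR",)),
    },
    duplicate_version_rate=0.2,   # 20% of cases get an extra, older version
    profile_duplicate_rate=0.1,   # 10% get a clone under a new case number
    seed=42,
)

manifest = generate(config, "scratch/example_dataset")

print(f"unique cases       : {manifest.n_unique_cases}")
print(f"report versions    : {len(manifest.frame)}")
print(f"planted duplicates : {len(manifest.frame) - manifest.n_unique_cases}")
for drug in config.drug_catalog:
    table = manifest.empirical_table(drug)
    print(
        f"{drug:<11} planted table (a={table.a}, b={table.b}, c={table.c}, d={table.d})"
        f"  empirical ROR {manifest.empirical_ror(drug):.2f}"
    )

# The empirical ROR is the ground-truth value the pipeline should recover
# EXACTLY once duplicates are removed (sampling noise moves it around the
# configured true_ror; dedup errors would break the exact match).
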