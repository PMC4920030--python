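"""File-based workflow: simulate to VCF + PED, reload, filter, test, write TSVs.

The same pipeline is available from a shell as
``conada simulate`` / ``conada run``; this script drives it from Python.
"""

import tempfile
from pathlib import Path

import pandas as pd

from conada import (
    PopulationModel,
    SequentialConfig,
    StudyDesign,
    filter_by_maf,
    generate_study,
    load_dataset,
    run_conada,
    write_pedigree,
    write_results,
    write_vcf,
)

workdir = Path(tempfile.mkdtemp())
design = StudyDesign(n_trios=50, n_controls=50, causal_fraction=0.0)
dataset, _ = generate_study(design, PopulationModel(n_sites=20, pool_size=500), seed=2)

write_vcf(dataset, workdir / "study.vcf")
write_pedigree(dataset, workdir / "study.ped")
print(f"wrote study.vcf + study.ped under {workdir}")

reloaded = load_dataset(workdir / "study.vcf", workdir / "study.ped")
analysis = filter_by_maf(reloaded, 0.05)
print(f"reloaded {analysis.n_trios} trios; {analysis.n_variants} variants pass MAF <= 0.05")

result = run_conada(analysis, mode="PC", cfg=SequentialConfig(b_min=100, b_max=1000, seed=3))
variant_path = write_results(result, workdir / "region.tsv")
print(f"adjusted P = {result.adjusted_p:.4g} (B = {result.b_used})")
print(pd.read_csv(variant_path, sep="\t").head().to_string(index=False))
print("Columns p / weight are the per-variant P-values and weights entering the score.")
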