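"""Reading study data: delimited per-subject tables and VCF.

Builds a small delimited dataset and an X-chromosome VCF on the fly,
reads both through the package's readers (note how hemizygous males are
handled), and runs XCMAX4 with an extra covariate.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from xcmax4 import SimulationConfig, read_tabular, run_xcmax4, simulate_dataset, validate

tmp = Path(tempfile.mkdtemp())

# --- delimited per-subject table -----------------------------------------
sim = simulate_dataset(SimulationConfig(beta=0.25, n_cases=400, n_controls=400), seed=3)
df = pd.DataFrame({
    "id": [f"s{i}" for i in range(sim.n)],
    "sex": sim.sex,
    "phenotype": sim.phenotype,
    "genotype": sim.genotype,
    "x3": sim.covariates[:, 2],
})
df.loc[3, "genotype"] = np.nan          # a missing call
path = tmp / "cohort.csv"
df.to_csv(path, index=False)

data = read_tabular(path, covariates=["x3"])
report = validate(data)
print(f"read {report.n} subjects ({report.n_cases} cases), "
      f"{report.n_dropped_missing} dropped by listwise deletion, flags: {report.flags}")
res = run_xcmax4(data)
print(f"XCMAX4: z = {res.statistic:.3f}, p = {res.p_value:.3e} "
      f"(attained by {res.attained_coding})")

# --- VCF with haploid and diploid-coded males ----------------------------
try:
    from xcmax4 import read_vcf

    vcf = tmp / "chrX.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n##contig=<ID=X>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tf1\tf2\tm1\tm2\tm3\n"
        "X\t100\trs1\tC\tT\t.\tPASS\t.\tGT\t0/1\t1/1\t1\t1/1\t0/1\n"
    )
    info = pd.DataFrame({
        "sample": ["f1", "f2", "m1", "m2", "m3"],
        "sex": [1, 1, 0, 0, 0],
        "phenotype": [1, 0, 1, 0, 1],
    })
    d = read_vcf(vcf, info)
    print(f"\nVCF: kept {d.n} of 5 samples; genotypes {d.genotype.tolist()}")
    print("m1 (haploid '1') and m2 (diploid '1/1') both count one risk-allele "
          "copy; the heterozygous male call m3 is a hemizygosity artifact and "
          "was dropped as missing.")
except ImportError:
    print("\n(cyvcf2 not installed; VCF part skipped)")
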