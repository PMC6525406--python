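"""Filter a FASTQ through the three read-removal rules.

Reads are removed whole when (1) >=10% of bases are N, (2) >50% of bases are
below phred 5, or (3) more than 10 nt align to the adapter with <=10%
mismatches. Here the input is synthetic with 15% of reads planted in each
failure class, so the expected kept fraction is ~55%.
"""

from pathlib import Path

import radpop as rp
from radpop.qc import filter_fastq_file

ADAPTER = "AGATCGGAAGAGC"
out = Path("scratch/example_qc")
out.mkdir(parents=True, exist_ok=True)

rp.simulate_reads(
    n_reads=1000,
    read_len=150,
    n_frac_planted=0.15,
    lowq_frac_planted=0.15,
    adapter=ADAPTER,
    adapter_insert_len=12,
    adapter_frac_planted=0.15,
    seed=2,
    fastq_path=out / "raw.fastq",
    truth_path=out / "truth.tsv",
)
report = filter_fastq_file(out / "raw.fastq", out / "clean.fastq", ADAPTER)

print(f"reads in:            {report.total_in}")
print(f"removed, N rule:     {report.removed_n_rule}")
print(f"removed, quality:    {report.removed_quality_rule}")
print(f"removed, adapter:    {report.removed_adapter_rule}")
print(f"kept:                {report.kept}")
# Each planted class is caught by exactly its own rule; kept == planted clean.
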