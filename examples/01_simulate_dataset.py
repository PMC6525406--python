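"""Simulate a 5-population SNP dataset with a known tree and one admixture
pulse, and write it as VCF + population map.

Frequencies drift down the tree under the Balding-Nichols beta model
(Var = c p(1-p) per branch), then 25% of population A's ancestry is replaced
by population C. Genotypes are Hardy-Weinberg draws with Poisson depth.
"""

from pathlib import Path

import radpop as rp
from radpop.simulate import write_popmap
from radpop.snp_matrix import write_vcf
from radpop.trees import Tree

out = Path("scratch/example_data")
out.mkdir(parents=True, exist_ok=True)

tree = Tree.from_newick("(((A:0.05,B:0.05):0.03,C:0.08):0.03,(D:0.06,E:0.2):0.05);")
config = rp.SimulationConfig(
    tree=tree,
    n_sites=20_000,
    n_per_pop={p: 8 for p in "ABCDE"},
    admixture_events=[("C", "A", 0.25)],
    inbreeding_f={"B": 0.5},
    miss_rate=0.05,
    depth_mean=16.0,
    seed=1,
)
truth = rp.simulate_frequencies(config)
gm = rp.sample_genotypes(truth)
write_vcf(gm, out / "simulated.vcf")
write_popmap(gm.popmap, out / "popmap.tsv")

print(f"simulated {config.n_sites} sites; {gm.n_sites} polymorphic after sampling")
print(f"({truth.n_monomorphic_discarded} sites were monomorphic in the sample and dropped)")
print(f"samples: {gm.n_samples} diploids in {len(gm.populations)} populations")
print(f"wrote {out/'simulated.vcf'} and {out/'popmap.tsv'}")
# The VCF + popmap pair is the input every downstream example consumes.
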