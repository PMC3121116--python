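"""Generate the standard planted-truth benchmark and inspect its shape.

The benchmark mimics a two-strain rat liver time course: 300 genes, two
strains (case/control), 5 ages grouped into three segments, 5 replicates.
Selected candidate networks are planted "active" (their genes follow the
network's own structural equations) and 25 genes per segment receive a
case-strain expression shift.
"""

from netscreen import standard_benchmark

bundle = standard_benchmark(seed=1)

print(f"expression matrix: {bundle.expression.values.shape[0]} genes x "
      f"{bundle.expression.values.shape[1]} samples")
print(f"candidate networks: {len(bundle.networks)}")
sizes = sorted(n.n_v for n in bundle.networks)
print(f"network sizes (nodes): min={sizes[0]}, median={sizes[len(sizes)//2]}, "
      f"max={sizes[-1]}")

print("\nplanted active networks (name, strain, segment):")
for name, strain, seg in sorted(bundle.truth.active, key=lambda t: (t[2], t[1])):
    print(f"  {name:8s} {strain:8s} {seg}")

n_de = len({g for g, _, _ in bundle.truth.de})
print(f"\nplanted DE genes: {n_de} distinct genes "
      f"({len(bundle.truth.de)} (gene, segment) pairs)")
print("\nThese (network, strain, segment) triples are what the screening "
      "pipeline should recover; everything else should stay quiet.")
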