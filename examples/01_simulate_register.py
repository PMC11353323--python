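"""Generate a synthetic psychiatric-care register and describe it.

The generator emulates a national register: ~98 municipalities, three
provider types, individuals attending on average ~2.2 providers with
care-share weights, ~30% hospitalised, and counts produced by the two-part
(hurdle) model with known variance components.
"""

from mmhurdle import GeneratorConfig, generate, summarize

ds = generate(GeneratorConfig(n_individuals=5000), seed=1)
s = summarize(ds)

print(f"individuals:            {s['n_individuals']}")
print(f"providers:              {s['n_hcps']}")
print(f"municipalities:         {s['n_municipalities']}")
print(f"hospitalised fraction:  {s['hospitalised_fraction']:.3f}   (target 0.30)")
print(
    "hospitalisations mean (SD) among hospitalised: "
    f"{s['mean_hospitalisations_among_hospitalised']:.2f} "
    f"({s['sd_hospitalisations_among_hospitalised']:.2f})"
)
print(f"mean distinct providers per individual: {s['mean_distinct_hcps']:.2f}")
print("distinct-provider distribution (share):")
for k, p in list(s["hcp_count_distribution"].items())[:6]:
    print(f"  {k} provider(s): {p:.3f}")
# The fractions mirror the emulated register: most individuals split care
# over two or three providers, and the true generating parameters are kept
# in ds.truth for recovery testing.
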