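"""Parameter counts of the detector variants.

Builds the baseline network and the attention-augmented variants at the
standard 80-class head and reports learnable-scalar totals in millions —
the architecture-level numbers that identify each variant.
"""

from strawdet import ModelConfig, build_model, count_parameters, count_parameters_m

VARIANTS = [
    ("baseline, scale n", dict(scale="n")),
    ("baseline, scale s", dict(scale="s")),
    ("+ SE-MSDWA (backbone end)", dict(scale="s", use_se_msdwa=True)),
    ("+ CGFM (4 neck nodes)", dict(scale="s", use_cgfm=True)),
    ("full model (both blocks)", dict(scale="s", use_se_msdwa=True, use_cgfm=True)),
]

base = None
for name, kw in VARIANTS:
    model = build_model(ModelConfig(num_classes=80, **kw))
    n = count_parameters(model)
    if kw == {"scale": "s"}:
        base = n
    delta = f"  (+{(n - base) / 1e6:.2f} M over baseline)" if base and n > base else ""
    print(f"{name:28s} {count_parameters_m(model):6.2f} M  = {n:>10,d}{delta}")

print()
print("Counts are exact enumerations of learnable scalars; the s-scale")
print("baseline and the full model carry the two attention blocks' costs")
print("(~0.57 M for the backbone block, ~6.96 M for the four fusion nodes).")
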