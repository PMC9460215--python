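"""Print the generator and classifier architectures with shape traces.

The declarative specs are validated against their declared per-layer
output sizes; the classifier's conv stack maps the 10,000-sample frame
down to a 37-sample map before the 3-way softmax head.
"""

from bowelwarn.model import classifier_spec, generator_spec

for spec in (generator_spec(), classifier_spec(K=2)):
    spec.validate()
    print(f"{spec.name}: input {spec.input_shape}")
    shapes = iter(spec.trace())
    for layer in spec.layers:
        if layer.layer_type in ("batch_norm", "activation_only"):
            print(f"  {layer.layer_type:16s} (shape preserved)")
            continue
        length, channels = next(shapes)
        extra = ""
        if layer.layer_type == "conv1d":
            extra = (f" k{layer.kernel}/s{layer.stride}/p{layer.padding}"
                     f" {layer.activation}")
        print(f"  {layer.layer_type:16s}{extra:22s} -> "
              f"{length} x {channels}")
    print()
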