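"""Receptive fields of the three cascade networks, two independent ways.

Builds the default WNet/TNet/ENet blueprints, computes each receptive
field analytically (exact interval propagation through the layer graph),
then realizes a slim copy of the network and measures the same quantity by
impulse probing (support of the input gradient of one central output
voxel).  The two routes must agree voxel-for-voxel.
"""

from tumorcascade import (
    compute_receptive_field,
    make_blueprint,
    probe_receptive_field,
    realize,
    search_dilation_schedules,
)

PROBE_EXTENTS = {"WNet": (224, 224, 13), "TNet": (224, 224, 13), "ENet": (128, 128, 13)}

for variant in ("WNet", "TNet", "ENet"):
    blueprint = make_blueprint(variant, C0=2)  # channel width does not matter here
    analytic = tuple(compute_receptive_field(blueprint))
    probed = tuple(probe_receptive_field(realize(blueprint, seed=0), PROBE_EXTENTS[variant]))
    print(f"{variant}: analytic {analytic}  probed {probed}  "
          f"schedule {blueprint.dilation_schedule}")

# The per-block dilations are not unique: the constraint search enumerates
# every schedule that reproduces the in-plane extent with the fixed layout.
alternatives = search_dilation_schedules("ENet", max_results=3)
print(f"three of the ENet schedules reaching 113 in-plane: {alternatives}")
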