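"""The measurement error budget of the stress / strain / modulus chain.

The modulus is a ratio G = sigma / gamma of two independently measured
quantities, so its relative error is the quadrature sum of the flow-field
error (which enters the stress linearly) and the strain noise floor.  A
second, systematic bound comes from not knowing each tracer's height within
the microscope's depth of field.
"""

import strobomech as sm

# representative values for a real experiment: ~30% flow-field residual
# error and ~5% blank-area strain noise
flow_error = 0.30
strain_error = 0.05
modulus_error = sm.propagate_errors(flow_error, strain_error)
print(f"flow-field error          : {100 * flow_error:.0f}%")
print(f"strain noise floor        : {100 * strain_error:.0f}%")
print(f"propagated modulus error  : {100 * modulus_error:.1f}%  (~30%)")

dof_bias = sm.depth_of_field_bias(depth_of_field_um=0.87, bead_radius_um=1.5)
print(f"depth-of-field stress bias: up to {100 * dof_bias:.0f}%  (~60%), "
      "mitigated by tracer sedimentation")
# On synthetic data the same quantities are *measured*: the pipeline report
# carries the flow residual (typically <1% with ideal tracers) and the
# blank-area strain ratio (a few percent at default noise).
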