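# Coupled 1:3 arterial-venous demonstration run.
#
# A single arterial channel drains through the capillary-bed coupling into
# three venous inlet channels of equal cross-section.  Pressure-drop
# fractions are sampled from [0.3, 0.7] with the seed below; velocity scale
# factors follow from the fixture's own link lengths.
schema_version = 1

[geometry]
fixture = "one_to_n"
n = 3

[units]
dx = 1e-4       # 0.1 mm lattice spacing
dt = 1.5e-4     # s; gives tau ~ 0.65 at blood viscosity
rho_ref = 1050.0
nu = 3.3e-6
v_max = 0.01    # m/s expected peak, Ma ~ 0.045

[run]
n_steps = 3000
output_dir = "out/one_to_three"

[coupling]
seed = 1
exchange_period = 10
dp_range = [0.3, 0.7]
gain = 10.0
P0 = 1.0

[[boundary]]
instance = "arterial"
patch = 0          # arterial inlet
kind = "velocity"
value = 0.005      # m/s

[[boundary]]
instance = "arterial"
patch = 1          # arterial outlet (coupled; pressure closure underneath)
kind = "pressure"
value = 1.0        # relative to the lattice reference pressure

[[boundary]]
instance = "venous"
patch = 3          # venous outlet
kind = "pressure"
value = 1.0
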