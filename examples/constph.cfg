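# constph physical defaults (flat key = value; flags override)

# continuum electrostatics
eps_in = 2            # solute dielectric
eps_out = 80          # solvent dielectric
ionic_strength = 0.1  # mol/L, 1:1 salt
temperature = 310     # K
convergence_tol = 0.01  # kT/e
nodes_per_side = 81
coarse_spacing = 0.1  # nm
fine_spacing = 0.025  # nm
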