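# nanoyap default model parameters, version 1.
#
# Patch-compartment surrogate of the 15-species YAP/TAZ mechanotransduction
# network (PM / cytosol / NE / nucleoplasm).  Curvature-dependent rate laws
# (integrin endocytosis, N-WASP actin polymerization) and the stretch-gated
# NPC transport law carry the published sensitivities; the upstream
# FAK -> RhoA -> ROCK -> (mDia, myosin) -> (LIMK -> cofilin) -> actin chain
# follows the structure of earlier well-mixed YAP/TAZ mechanotransduction
# models, with rate constants scaled for the surface-to-volume form used
# here.  Units are annotated per key.  Every key listed in the loader
# manifest must be present; missing keys raise a configuration error.

meta:
  version: 1
  notes: >
    Surface reactions enter the cytosolic balance as
    (patch area / compartment volume) * per-area rate.  Concentrations are
    uM for volume species and per-um^2 densities for surface species.

cell:
  v_cyto_um3: 2300.0        # cytosolic volume, U2OS-scale
  v_nuc_um3: 550.0          # nuclear volume, U2OS-scale
  nuclear_aspect_ratio: 2.21  # oblate spheroid a/b (equatorial/vertical)
  apical_clearance_um: 0.8  # nucleus top must stay this far below apical PM

pm_curvature:
  rho_i_max_per_um2: 1000.0  # maximal bound-integrin density
  h0_per_um: 5.0             # endocytosis curvature sensitivity (best fit)
  k_f_per_s: 0.015           # stiffness-independent FAK phosphorylation
  k_sf_per_s: 0.379          # stiffness-dependent FAK phosphorylation
  c_kpa: 3.25                # stiffness sensitivity of FAK activation
  k_df_per_s: 0.035          # FAK dephosphorylation
  ell_pm_um: 3.0             # membrane-proximal reaction depth converting
                             # the s^-1 FAK rate to a per-area velocity

nwasp:
  k_nwasp_um_per_s: 0.01     # flat-membrane polymerization velocity (best fit)
  h_nwasp_per_um: 2.0        # N-WASP curvature scale (500-nm nanobar side)

network:
  fak_tot_uM: 1.0
  rhoa_tot_per_um2: 33.6     # total RhoA density at the PM
  k_fkrho_per_s: 0.0168      # basal RhoA GEF activity
  gamma_per_uM5: 77.56       # pFAK^5 amplification of RhoA activation
  k_drho_per_s: 0.625        # RhoA-GTP hydrolysis
  rock_tot_uM: 1.0
  k_rock_um_per_s: 1.0       # ROCK activation velocity at the PM
  k_drock_per_s: 0.8
  mdia_tot_uM: 0.8
  k_mdia_um_per_s: 0.2       # mDia activation velocity at the PM
  k_dmdia_per_s: 0.1
  myo_tot_uM: 5.0
  k_myo0_per_s: 0.002        # basal myosin activation
  k_myo_per_uM_s: 0.12       # ROCK-dependent myosin activation
  k_dmyo_per_s: 0.067
  limk_tot_uM: 2.0
  k_limk_per_uM_s: 0.07      # ROCK-dependent LIMK activation
  k_dlimk_per_s: 0.1
  cof_tot_uM: 2.0
  k_turn_per_s: 0.04         # cofilin dephosphorylation (reactivation)
  k_cat_per_uM_s: 0.34       # LIMK-catalyzed cofilin phosphorylation
  k_mcof_uM: 4.0             # Michaelis constant of LIMK on cofilin
  actin_tot_uM: 17.9         # conserved F + G actin pool
  k_ra_per_s: 0.004          # basal actin polymerization
  alpha_mdia: 4.0            # mDia enhancement of polymerization
  k_dep_per_s: 0.03          # basal depolymerization
  alpha_cof: 1.5             # cofilin enhancement of depolymerization
  lam_tot_per_um2: 3500.0    # total lamin A density at the NE
  k_flam_per_s: 0.1          # stiffness-driven lamin A dephosphorylation
  k_lam_e_kpa: 5.0           # half-saturation cytosolic stiffness for lamin
  k_dlam_per_s: 0.05         # lamin A rephosphorylation (release)
  npc_tot_per_um2: 10.6      # total NPC density at the NE
  k_fnpc: 1.0e-6             # NPC opening, per (uM^2 * lamin um^-2 * s)
  k_rnpc_per_s: 0.05         # NPC closing
  k_cn_per_uM2_s: 0.05       # stress-fiber-driven YAP/TAZ dephosphorylation
  k_nc_per_s: 0.1            # YAP/TAZ rephosphorylation in the cytosol

transport:
  k_inb_um_per_s: 0.001      # basal NPC import velocity
  k_in_um3_per_s: 0.01       # NPC-activation-dependent import, per NPC density
  k_out_npc_um_per_s: 0.008  # NPC export velocity
  alpha_0: 5.0               # NE-stretch sensitivity of NPC import
  k_bind_per_s: 4.0          # nuclear binding (e.g. TEAD) of YAP/TAZ
  k_unbind_per_s: 1.0        # nuclear unbinding; upsilon = 1 + kbind/kunbind

readouts:
  c_e_kpa: 0.22              # cytosolic stiffness prefactor, E = c_E [F]^2.6
  stiffness_exponent: 2.6
  c_sf: 1.0                  # stress-fiber prefactor, SF = c_SF [F][MyoA]

initial_state:
  pfak_uM: 0.3
  rhoa_gtp_per_um2: 1.0
  rock_a_uM: 0.0
  mdia_a_uM: 0.0
  myo_a_uM: 0.2
  limk_a_uM: 0.1
  cofilin_np_uM: 1.8
  factin_uM: 0.5
  lamin_a_per_um2: 350.0
  npc_a_per_um2: 0.5
  yap_p_uM: 0.65
  yap_cyto_uM: 0.3
  yap_nuc_uM: 0.7
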