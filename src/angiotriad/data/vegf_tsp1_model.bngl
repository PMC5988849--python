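begin model

begin parameters
  kon_VEGF_R2 0.005
  koff_VEGF_R2 0.001
  kon_VEGF_R1 0.01
  koff_VEGF_R1 0.001
  kc_VR2 3e-06
  kc_VR1R2 1.5e-06
  kVEGFNRP1_on 0.0001
  kVEGFR2NRP1_off 0.001
  kon_TSP1_CD47 0.01
  koff_TSP1_CD47 0.00025
  kon_R1NRP1 1e-05
  koff_R1NRP1 0.01
  kon_R2CD47 3e-05
  koff_R2CD47 0.003
  kc_RR 1e-06
  kd_RR 0.01
  kp_R2 0.01
  kdp_s 0.05
  kdp_i 0.0006
  kr2_i 0.02
  kr2_si 0.00014
  kt12 0.0006
  kt2r 0.0015
  krec 0.0015
  kmisc_rec 0.001
  kre_off 0.005
  kdeg_ligand_endo 0.001
  kdeg_i0 0.0006
  kdeg_i0noP 0.0004
  ksingleR2_syn 0.00014
  R2_total_0 6000.0
  fTSP1_i2r 1.0
  fTSP1_deg 1.0
  fTSP1_dp 1.0
  Src_0 1.0
  kp_Src 0.05
  km_Src 1500.0
  kdp_Src 0.02
  drive_basal 5.0
  Axl_0 1.0
  kp_SrcAxl 0.2
  kdp_SrcAxl 0.1
  kp_Axlauto 0.05
  kdp_autoAxl 0.05
  PI3K_0 0.5
  kon_PI3KAxl 0.2
  koff_PI3KAxl 0.1
  PIP2_0 10.0
  kcat_PI3KPIP2 0.2
  km_PIP2PI3K 5.0
  PTEN_0 0.5
  kcat_PTENPIP3 0.15
  km_PIP3PTEN 1.0
  Akt_0 1.0
  kon_AktPIP3 0.2
  koff_Akt 0.1
  kp_S473mTOR 0.1
  kdp_S473 0.1
  PDK1_0 0.5
  kp_T308PDK1 0.2
  kdp_T308 0.1
  PLC_0 1.0
  kp_PLC 0.002
  km_PLC 600.0
  kdp_PLC 0.001
  kcat_PLCgDAG 0.2
  kdeg_ip3 0.05
  IP3_rest 0.05
  km_ip3 3.0
  Iip3R_amp 1.2
  ICRAC_amp 2.0
  v_SERCA 10.0
  km_serca 0.25
  IPMCA_amp 5.0
  km_pmca 0.3
  Ca_rest 0.1
  Ca_ER_rest 400.0
  beta_er 5.0
  CaM_0 10.0
  kon_CaCaM 0.5
  koff_CaCaM 1.0
  eNOS_0 1.0
  kon_eNOSCaCaM 0.1
  koff_eNOSCaCaM 0.3
  kp_eNOS 3.0
  kdp_eNOS 0.1
end parameters

begin molecule types
  VEGF(r,r,nrp1bd)
  VEGFR2(L,Y1175~u~p,c)
  VEGFR1(L,nrp1bd,c)
  NRP1(l)
  CD47(vegfr2bd,tsp1bd)
  TSP1(cd47bd)
end molecule types

begin seed species
  $@PM:VEGF() 0.0
  $@PM:TSP1() 0.0
  @PM:VEGFR2(Y1175~u) 6000.0
  @PM:VEGFR1() 1800.0
  @PM:NRP1() 20000.0
  @PM:CD47() 10000.0
end seed species

begin observables
  Molecules pR2 VEGFR2(Y1175~p)
end observables

begin reaction rules
  vegf_r2_bind: VEGF(r) + VEGFR2(L) -> VEGF(r!1).VEGFR2(L!1) kon_VEGF_R2 exclude_reactants(1,VEGF(r!+)) exclude_reactants(1,VEGF(nrp1bd!+)) compartments(PM)
  vegf_r2_unbind: VEGF(r!1).VEGFR2(L!1) -> VEGF(r) + VEGFR2(L) koff_VEGF_R2 compartments(PM)
  vegf_r1_bind: VEGF(r) + VEGFR1(L) -> VEGF(r!1).VEGFR1(L!1) kon_VEGF_R1 exclude_reactants(1,VEGF(r!+)) exclude_reactants(1,VEGF(nrp1bd!+)) compartments(PM)
  vegf_r1_unbind: VEGF(r!1).VEGFR1(L!1) -> VEGF(r) + VEGFR1(L) koff_VEGF_R1 compartments(PM)
  vegf_nrp1_to_r2: VEGF(r,r,nrp1bd!+) + VEGFR2(L) -> VEGF(r!1,r,nrp1bd!+).VEGFR2(L!1) kc_VR2 compartments(PM)
  dimer_r2r2: VEGF(r!1,r).VEGFR2(L!1) + VEGFR2(L) -> VEGF(r!1,r!2).VEGFR2(L!1).VEGFR2(L!2) kc_VR2 compartments(PM)
  dimer_r1r2: VEGF(r!1,r).VEGFR1(L!1) + VEGFR2(L) -> VEGF(r!1,r!2).VEGFR1(L!1).VEGFR2(L!2) kc_VR1R2 compartments(PM)
  dimer_r2r1: VEGF(r!1,r).VEGFR2(L!1) + VEGFR1(L) -> VEGF(r!1,r!2).VEGFR2(L!1).VEGFR1(L!2) kc_VR1R2 compartments(PM)
  vegf_nrp1_couple: VEGF(nrp1bd,r!+) + NRP1(l) -> VEGF(nrp1bd!1,r!+).NRP1(l!1) kVEGFNRP1_on compartments(PM)
  vegf_nrp1_uncouple: VEGF(nrp1bd!1).NRP1(l!1) -> VEGF(nrp1bd) + NRP1(l) kVEGFR2NRP1_off compartments(PM)
  r1_nrp1_couple: VEGFR1(nrp1bd) + NRP1(l) -> VEGFR1(nrp1bd!1).NRP1(l!1) kon_R1NRP1 compartments(PM)
  r1_nrp1_uncouple: VEGFR1(nrp1bd!1).NRP1(l!1) -> VEGFR1(nrp1bd) + NRP1(l) koff_R1NRP1 compartments(PM)
  r2_cd47_couple: VEGFR2(c) + CD47(vegfr2bd) -> VEGFR2(c!1).CD47(vegfr2bd!1) kon_R2CD47 compartments(PM)
  r2_cd47_uncouple: VEGFR2(c!1).CD47(vegfr2bd!1) -> VEGFR2(c) + CD47(vegfr2bd) koff_R2CD47 compartments(PM)
  tsp1_bind: TSP1(cd47bd) + CD47(tsp1bd,vegfr2bd!+) -> TSP1(cd47bd!1).CD47(tsp1bd!1,vegfr2bd!+) kon_TSP1_CD47 compartments(PM)
  tsp1_unbind: TSP1(cd47bd!1).CD47(tsp1bd!1) -> TSP1(cd47bd) + CD47(tsp1bd) koff_TSP1_CD47 compartments(PM)
  rr_couple: VEGFR2(c) + VEGFR2(c) -> VEGFR2(c!1).VEGFR2(c!1) kc_RR compartments(PM)
  rr_uncouple: VEGFR2(c!1).VEGFR2(c!1) -> VEGFR2(c) + VEGFR2(c) kd_RR compartments(PM)
  r2_phos: VEGFR2(L!1,Y1175~u).VEGF(r!1,r!2).VEGFR2(L!2) -> VEGFR2(L!1,Y1175~p).VEGF(r!1,r!2).VEGFR2(L!2) kp_R2 compartments(PM)
  r2_dephos_pm: VEGFR2(Y1175~p) -> VEGFR2(Y1175~u) kdp_s exclude_reactants(1,TSP1(cd47bd!+)) compartments(PM)
  r2_dephos_pm_tsp1: VEGFR2(Y1175~p) -> VEGFR2(Y1175~u) kdp_s*fTSP1_dp include_reactants(1,TSP1(cd47bd!+)) compartments(PM)
  r2_dephos_endo: VEGFR2(Y1175~p) -> VEGFR2(Y1175~u) kdp_i compartments(SE1,SE2,RE)
  internalize_dimer: VEGFR2(L!1).VEGF(r!1,r!2).VEGFR2(L!2) -> @SE1:VEGFR2(L!1).VEGF(r!1,r!2).VEGFR2(L!2) kr2_i compartments(PM) TotalRate
  internalize_const: VEGFR2() -> @SE1:VEGFR2() kr2_si compartments(PM) TotalRate
  se1_to_se2: VEGFR2() -> @SE2:VEGFR2() kt12 compartments(SE1) TotalRate
  se2_to_re: VEGFR2() -> @RE:VEGFR2() kt2r include_reactants(1,NRP1()) exclude_reactants(1,TSP1(cd47bd!+)) compartments(SE2) TotalRate
  se2_to_re_tsp1: VEGFR2() -> @RE:VEGFR2() kt2r*fTSP1_i2r include_reactants(1,NRP1()) include_reactants(1,TSP1(cd47bd!+)) compartments(SE2) TotalRate
  recycle: VEGFR2() -> @PM:VEGFR2() krec exclude_reactants(1,VEGFR2(Y1175~p)) compartments(RE) TotalRate
  deg_p: VEGFR2(Y1175~p) -> 0 kdeg_i0 exclude_reactants(1,TSP1(cd47bd!+)) compartments(SE1,SE2) DeleteMolecules
  deg_p_tsp1: VEGFR2(Y1175~p) -> 0 kdeg_i0*fTSP1_deg include_reactants(1,TSP1(cd47bd!+)) compartments(SE1,SE2) DeleteMolecules
  deg_u: VEGFR2(Y1175~u) -> 0 kdeg_i0noP exclude_reactants(1,TSP1(cd47bd!+)) compartments(SE1,SE2) DeleteMolecules
  deg_u_tsp1: VEGFR2(Y1175~u) -> 0 kdeg_i0noP*fTSP1_deg include_reactants(1,TSP1(cd47bd!+)) compartments(SE1,SE2) DeleteMolecules
  re_vegf_r2_unbind: VEGF(r!1).VEGFR2(L!1) -> VEGF(r) + VEGFR2(L) kre_off compartments(RE)
  re_vegf_r1_unbind: VEGF(r!1).VEGFR1(L!1) -> VEGF(r) + VEGFR1(L) kre_off compartments(RE)
  re_vegf_nrp1_unbind: VEGF(nrp1bd!1).NRP1(l!1) -> VEGF(nrp1bd) + NRP1(l) kre_off compartments(RE)
  re_tsp1_unbind: TSP1(cd47bd!1).CD47(tsp1bd!1) -> TSP1(cd47bd) + CD47(tsp1bd) kre_off compartments(RE)
  vegf_endo_decay: VEGF(r,r,nrp1bd) -> 0 kdeg_ligand_endo compartments(SE1,SE2,RE) DeleteMolecules
  tsp1_endo_decay: TSP1(cd47bd) -> 0 kdeg_ligand_endo compartments(SE1,SE2,RE) DeleteMolecules
  return_r1_se1: VEGFR1() -> @PM:VEGFR1() kmisc_rec exclude_reactants(1,VEGFR2()) compartments(SE1) TotalRate
  return_nrp1_se1: NRP1() -> @PM:NRP1() kmisc_rec exclude_reactants(1,VEGFR2()) exclude_reactants(1,VEGFR1()) compartments(SE1) TotalRate
  return_cd47_se1: CD47() -> @PM:CD47() kmisc_rec exclude_reactants(1,VEGFR2()) compartments(SE1) TotalRate
  return_r1_se2: VEGFR1() -> @PM:VEGFR1() kmisc_rec exclude_reactants(1,VEGFR2()) compartments(SE2) TotalRate
  return_nrp1_se2: NRP1() -> @PM:NRP1() kmisc_rec exclude_reactants(1,VEGFR2()) exclude_reactants(1,VEGFR1()) compartments(SE2) TotalRate
  return_cd47_se2: CD47() -> @PM:CD47() kmisc_rec exclude_reactants(1,VEGFR2()) compartments(SE2) TotalRate
  return_r1_re: VEGFR1() -> @PM:VEGFR1() kmisc_rec exclude_reactants(1,VEGFR2()) compartments(RE) TotalRate
  return_nrp1_re: NRP1() -> @PM:NRP1() kmisc_rec exclude_reactants(1,VEGFR2()) exclude_reactants(1,VEGFR1()) compartments(RE) TotalRate
  return_cd47_re: CD47() -> @PM:CD47() kmisc_rec exclude_reactants(1,VEGFR2()) compartments(RE) TotalRate
  r2_synthesis: 0 -> @PM:VEGFR2(L,Y1175~u,c) ksingleR2_syn*R2_total_0
end reaction rules

end model
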