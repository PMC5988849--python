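"""The VEGF--VEGFR2--TSP1 signaling model.

Assembles the receptor-layer rule set (ligand binding, dimerization,
constitutive coupling, phosphorylation, multi-compartment trafficking,
degradation and synthesis), the downstream Src/Axl/PI3K/Akt cascade, the
PLCgamma/IP3/Ca/CaM module and the two-step eNOS activation as one model
object, together with its nominal parameter set and the three TSP1--CD47
mechanism hooks:

``fTSP1_i2r``
    multiplies the signaling-endosome -> recycling-endosome transport rate
    of complexes that contain TSP1-bound CD47 (<= 1; 0 blocks transport).
``fTSP1_deg``
    multiplies endosomal VEGFR2 degradation rates for such complexes (>= 1).
``fTSP1_dp``
    multiplies the plasma-membrane VEGFR2 dephosphorylation rate for such
    complexes (phosphatase recruitment; >= 1).

Amount conventions: membrane/endosomal species in molecules per cell;
extracellular VEGF and TSP1 as clamped bath species in nM (events set the
dose); cytosolic cascade species in uM.  50 ng/ml VEGF is converted at an
assumed 45 kDa dimer mass to ~1.1 nM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .rulegraph import (
    ModelSignature,
    MoleculeType,
    RxnRule,
    SiteDef,
    SpeciesGraph,
    ValidationError,
    generate_network,
    parse_species,
)

__all__ = [
    "ParameterSet",
    "InitialState",
    "InterventionSpec",
    "ModelSpec",
    "build_model",
    "nominal_parameters",
    "signature",
    "receptor_rules",
    "downstream_rules",
    "calcium_fluxes",
    "CascadeDynamics",
    "VEGF_NG_ML_TO_NM",
]

# 50 ng/ml VEGF at an assumed 45 kDa dimer mass -> ~1.1 nM
VEGF_NG_ML_TO_NM = 1.0 / 45.0

MAX_STOICH = {("VEGFR1", "VEGFR2"): 2, "VEGF": 1, "NRP1": 2, "CD47": 2, "TSP1": 2}


# ---------------------------------------------------------------------------
# parameters

#: name -> (default value, unit, description); the receptor block is in
#: molecules/cell and s^-1, ligand on-rates in nM^-1 s^-1, the cascade in uM.
PARAMETER_TABLE: dict[str, tuple[float, str, str]] = {
    # --- ligand binding (bath ligands in nM) ---
    "kon_VEGF_R2": (5e-3, "1/(nM s)", "VEGF binding to VEGFR2 ligand site"),
    "koff_VEGF_R2": (1e-3, "1/s", "VEGF-VEGFR2 bond dissociation"),
    "kon_VEGF_R1": (1e-2, "1/(nM s)", "VEGF binding to VEGFR1"),
    "koff_VEGF_R1": (1e-3, "1/s", "VEGF-VEGFR1 bond dissociation"),
    "kc_VR2": (3e-6, "1/(molec s)", "membrane closure of receptor-bound VEGF onto VEGFR2"),
    "kc_VR1R2": (1.5e-6, "1/(molec s)", "membrane closure forming VEGFR1/VEGFR2 heterodimer"),
    "kVEGFNRP1_on": (1e-4, "1/(molec s)", "coupling of receptor-bound VEGF to NRP1"),
    "kVEGFR2NRP1_off": (1e-3, "1/s", "VEGF-NRP1 bond dissociation"),
    "kon_TSP1_CD47": (1e-2, "1/(nM s)", "TSP1 binding to VEGFR2-coupled CD47"),
    "koff_TSP1_CD47": (2.5e-4, "1/s", "TSP1-CD47 dissociation (Kd ~25 pM)"),
    # --- constitutive coupling ---
    "kon_R1NRP1": (1e-5, "1/(molec s)", "constitutive VEGFR1-NRP1 coupling"),
    "koff_R1NRP1": (1e-2, "1/s", "VEGFR1-NRP1 decoupling"),
    "kon_R2CD47": (3e-5, "1/(molec s)", "constitutive VEGFR2-CD47 coupling"),
    "koff_R2CD47": (3e-3, "1/s", "VEGFR2-CD47 decoupling"),
    "kc_RR": (1e-6, "1/(molec s)", "ligand-independent receptor-receptor coupling"),
    "kd_RR": (1e-2, "1/s", "ligand-independent receptor-receptor decoupling"),
    # --- phosphorylation ---
    "kp_R2": (0.01, "1/s", "VEGFR2 autophosphorylation in VEGF-bridged homodimer"),
    "kdp_s": (0.05, "1/s", "VEGFR2 dephosphorylation at the plasma membrane"),
    "kdp_i": (6e-4, "1/s", "VEGFR2 dephosphorylation in endosomes"),
    # --- trafficking ---
    "kr2_i": (0.02, "1/s", "internalization of VEGF-homodimerized VEGFR2 (PM->SE1)"),
    "kr2_si": (1.4e-4, "1/s", "constitutive VEGFR2 internalization (PM->SE1)"),
    "kt12": (6e-4, "1/s", "transport SE1->SE2"),
    "kt2r": (1.5e-3, "1/s", "NRP1-gated transport SE2->RE"),
    "krec": (1.5e-3, "1/s", "recycling RE->PM of unphosphorylated receptors"),
    "kmisc_rec": (1e-3, "1/s", "return of receptor-free partners from endosomes to PM"),
    "kre_off": (5e-3, "1/s", "ligand dissociation in the recycling endosome"),
    "kdeg_ligand_endo": (1e-3, "1/s", "decay of free ligand in endosomes"),
    "kdeg_i0": (6e-4, "1/s", "degradation of phosphorylated VEGFR2 from SE1/SE2"),
    "kdeg_i0noP": (4e-4, "1/s", "degradation of unphosphorylated VEGFR2 from SE1/SE2"),
    "ksingleR2_syn": (1.4e-4, "1/s", "VEGFR2 synthesis rate constant (x R2 total)"),
    "R2_total_0": (6000.0, "molec", "reference VEGFR2 total for the synthesis rule"),
    # --- TSP1 mechanism hooks ---
    "fTSP1_i2r": (1.0, "-", "TSP1 scaling of SE->RE transport (<=1)"),
    "fTSP1_deg": (1.0, "-", "TSP1 scaling of endosomal degradation (>=1)"),
    "fTSP1_dp": (1.0, "-", "TSP1 scaling of PM dephosphorylation (>=1)"),
    # --- TSAd/Src and Axl ---
    "Src_0": (1.0, "uM", "total TSAd/Src"),
    "kp_Src": (0.05, "1/s", "Src activation by phosphorylated VEGFR2 (saturating)"),
    "km_Src": (1500.0, "molec", "pR2 level for half-maximal Src activation"),
    "kdp_Src": (0.02, "1/s", "Src deactivation"),
    "drive_basal": (5.0, "molec", "constitutive kinase drive (basal activity)"),
    "Axl_0": (1.0, "uM", "total Axl-1"),
    "kp_SrcAxl": (0.2, "1/(uM s)", "Axl-1 site-1 phosphorylation by active Src"),
    "kdp_SrcAxl": (0.1, "1/s", "Axl-1 site-1 dephosphorylation"),
    "kp_Axlauto": (0.05, "1/s", "Axl-1 site-2 autophosphorylation"),
    "kdp_autoAxl": (0.05, "1/s", "Axl-1 site-2 dephosphorylation"),
    # --- PI3K / PIP3 / Akt ---
    "PI3K_0": (0.5, "uM", "total PI3K"),
    "kon_PI3KAxl": (0.2, "1/(uM s)", "PI3K recruitment/activation by doubly active Axl-1"),
    "koff_PI3KAxl": (0.1, "1/s", "PI3K inactivation"),
    "PIP2_0": (10.0, "uM", "total PIP2+PIP3 pool"),
    "kcat_PI3KPIP2": (0.2, "1/s", "PI3K catalytic rate on PIP2"),
    "km_PIP2PI3K": (5.0, "uM", "PIP2 Michaelis constant of PI3K"),
    "PTEN_0": (0.5, "uM", "total PTEN"),
    "kcat_PTENPIP3": (0.15, "1/s", "PTEN catalytic rate on PIP3"),
    "km_PIP3PTEN": (1.0, "uM", "PIP3 Michaelis constant of PTEN"),
    "Akt_0": (1.0, "uM", "total Akt"),
    "kon_AktPIP3": (0.2, "1/(uM s)", "Akt membrane recruitment by PIP3"),
    "koff_Akt": (0.1, "1/s", "Akt membrane release"),
    "kp_S473mTOR": (0.1, "1/s", "Akt S473 phosphorylation by mTOR (membrane Akt)"),
    "kdp_S473": (0.1, "1/s", "Akt S473 dephosphorylation"),
    "PDK1_0": (0.5, "uM", "total PDK1"),
    "kp_T308PDK1": (0.2, "1/(uM s)", "Akt T308 phosphorylation by PDK1 (requires pS473)"),
    "kdp_T308": (0.1, "1/s", "Akt T308 dephosphorylation"),
    # --- PLCgamma / IP3 / Ca ---
    "PLC_0": (1.0, "uM", "total PLCgamma"),
    "kp_PLC": (0.002, "1/s", "PLCgamma activation by phosphorylated VEGFR2 (saturating)"),
    "km_PLC": (600.0, "molec", "pR2 level for half-maximal PLCgamma activation"),
    "kdp_PLC": (0.001, "1/s", "PLCgamma deactivation"),
    "kcat_PLCgDAG": (0.2, "1/s", "IP3 production rate per active PLCgamma"),
    "kdeg_ip3": (0.05, "1/s", "IP3 degradation rate"),
    "IP3_rest": (0.05, "uM", "resting IP3"),
    "km_ip3": (3.0, "uM", "IP3 receptor half-activation"),
    "Iip3R_amp": (1.2, "1/s", "amplitude of IP3-receptor ER release"),
    "ICRAC_amp": (2.0, "uM/s", "amplitude of store-operated (CRAC) entry"),
    "v_SERCA": (10.0, "uM/s", "maximal SERCA pump rate"),
    "km_serca": (0.25, "uM", "SERCA half-activation"),
    "IPMCA_amp": (5.0, "uM/s", "maximal plasma-membrane Ca pump rate"),
    "km_pmca": (0.3, "uM", "PMCA half-activation"),
    "Ca_rest": (0.1, "uM", "resting cytosolic Ca"),
    "Ca_ER_rest": (400.0, "uM", "resting (full) ER Ca"),
    "beta_er": (5.0, "-", "cytosol/ER effective volume ratio"),
    # --- CaM and eNOS ---
    "CaM_0": (10.0, "uM", "total calmodulin"),
    "kon_CaCaM": (0.5, "1/(uM^2 s)", "Ca binding to calmodulin (cooperative, order 2)"),
    "koff_CaCaM": (1.0, "1/s", "Ca/CaM dissociation"),
    "eNOS_0": (1.0, "uM", "total eNOS"),
    "kon_eNOSCaCaM": (0.1, "1/(uM s)", "Ca/CaM binding to eNOS-caveolin (releases caveolin)"),
    "koff_eNOSCaCaM": (0.3, "1/s", "eNOS re-association with caveolin"),
    "kp_eNOS": (3.0, "1/(uM s)", "eNOS S1177 phosphorylation by doubly active Akt"),
    "kdp_eNOS": (0.1, "1/s", "eNOS S1177 dephosphorylation"),
}

#: parameters that multiply a rule rate only for TSP1-containing complexes
HOOK_PARAMS = ("fTSP1_i2r", "fTSP1_deg", "fTSP1_dp")


class ParameterSet(dict):
    """Named kinetic/amplitude parameters with units and validation."""

    def __init__(self, values: dict[str, float] | None = None):
        super().__init__({k: v for k, (v, _, _) in PARAMETER_TABLE.items()})
        if values:
            unknown = set(values) - set(PARAMETER_TABLE)
            if unknown:
                raise ValidationError(f"unknown parameters: {sorted(unknown)}")
            self.update(values)
        self.validate()

    def validate(self) -> None:
        for k, v in self.items():
            if k in HOOK_PARAMS:
                continue
            if v < 0:
                raise ValidationError(f"parameter {k} must be >= 0, got {v}")
        if not 0.0 <= self["fTSP1_i2r"] <= 1.0:
            raise ValidationError("fTSP1_i2r must be in [0, 1]")
        if self["fTSP1_deg"] < 1.0 or self["fTSP1_dp"] < 1.0:
            raise ValidationError("fTSP1_deg and fTSP1_dp must be >= 1")

    @property
    def kd_tsp1_cd47_nM(self) -> float:
        return self["koff_TSP1_CD47"] / self["kon_TSP1_CD47"]

    def unit(self, name: str) -> str:
        return PARAMETER_TABLE[name][1]

    def describe(self, name: str) -> str:
        return PARAMETER_TABLE[name][2]

    def copy(self) -> "ParameterSet":
        ps = ParameterSet()
        ps.update(self)
        return ps


def nominal_parameters(**overrides: float) -> ParameterSet:
    return ParameterSet(overrides or None)


# ---------------------------------------------------------------------------
# initial state and interventions


@dataclass
class InitialState:
    """Seed amounts (molecules/cell for receptors; nM for bath ligands)."""

    vegfr2_total: float = 6000.0
    cd47_total: float = 10000.0
    vegfr1_total: float = 1800.0
    nrp1_total: float = 20000.0
    vegf_nM: float = 0.0
    tsp1_nM: float = 0.0

    def validate(self) -> None:
        for name, v in vars(self).items():
            if v < 0:
                raise ValidationError(f"initial amount {name} must be >= 0")


@dataclass
class InterventionSpec:
    """In-silico interventions applied before/at stimulation."""

    tsp1_depletion_fraction: float = 0.0
    cd47_depletion_fraction: float = 0.0
    kd_scale_tsp1cd47: float = 1.0
    nrp1_knockout: bool = False
    chx: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.tsp1_depletion_fraction <= 1.0:
            raise ValidationError("tsp1_depletion_fraction must be in [0, 1]")
        if not 0.0 <= self.cd47_depletion_fraction <= 1.0:
            raise ValidationError("cd47_depletion_fraction must be in [0, 1]")
        if self.kd_scale_tsp1cd47 < 1.0:
            raise ValidationError("kd_scale_tsp1cd47 must be >= 1")


# ---------------------------------------------------------------------------
# molecule types and rules


def signature() -> ModelSignature:
    return ModelSignature(
        [
            MoleculeType("VEGF", (SiteDef("r"), SiteDef("r"), SiteDef("nrp1bd"))),
            MoleculeType("VEGFR2", (SiteDef("L"), SiteDef("Y1175", ("u", "p")), SiteDef("c"))),
            MoleculeType("VEGFR1", (SiteDef("L"), SiteDef("nrp1bd"), SiteDef("c"))),
            MoleculeType("NRP1", (SiteDef("l"),)),
            MoleculeType("CD47", (SiteDef("vegfr2bd"), SiteDef("tsp1bd"))),
            MoleculeType("TSP1", (SiteDef("cd47bd"),)),
        ]
    )


_TSP1_BOUND = "TSP1(cd47bd!+)"  # species-level marker: complex contains bound TSP1


def receptor_rules(sig: ModelSignature) -> list[RxnRule]:
    """The receptor-layer rule inventory (binding, dimerization, coupling,
    phosphorylation, trafficking, degradation, synthesis)."""
    R = RxnRule
    rules: list[RxnRule] = []

    # --- VEGF binding from the bath (fully free VEGF only) ---
    rules.append(
        R("vegf_r2_bind", ["VEGF(r)", "VEGFR2(L)"], ["VEGF(r!1).VEGFR2(L!1)"],
          "kon_VEGF_R2",
          exclude=[(0, "VEGF(r!+)"), (0, "VEGF(nrp1bd!+)")],
          compartments=["PM"], signature=sig)
    )
    rules.append(
        R("vegf_r2_unbind", ["VEGF(r!1).VEGFR2(L!1)"], ["VEGF(r)", "VEGFR2(L)"],
          "koff_VEGF_R2", compartments=["PM"], signature=sig)
    )
    rules.append(
        R("vegf_r1_bind", ["VEGF(r)", "VEGFR1(L)"], ["VEGF(r!1).VEGFR1(L!1)"],
          "kon_VEGF_R1",
          exclude=[(0, "VEGF(r!+)"), (0, "VEGF(nrp1bd!+)")],
          compartments=["PM"], signature=sig)
    )
    rules.append(
        R("vegf_r1_unbind", ["VEGF(r!1).VEGFR1(L!1)"], ["VEGF(r)", "VEGFR1(L)"],
          "koff_VEGF_R1", compartments=["PM"], signature=sig)
    )
    # NRP1-tethered VEGF captures VEGFR2 (membrane 2D event)
    rules.append(
        R("vegf_nrp1_to_r2", ["VEGF(r,r,nrp1bd!+)", "VEGFR2(L)"],
          ["VEGF(r!1,r,nrp1bd!+).VEGFR2(L!1)"], "kc_VR2",
          compartments=["PM"], signature=sig)
    )

    # --- VEGF-mediated dimer closure (membrane 2D events) ---
    rules.append(
        R("dimer_r2r2", ["VEGF(r!1,r).VEGFR2(L!1)", "VEGFR2(L)"],
          ["VEGF(r!1,r!2).VEGFR2(L!1).VEGFR2(L!2)"], "kc_VR2",
          compartments=["PM"], signature=sig)
    )
    rules.append(
        R("dimer_r1r2", ["VEGF(r!1,r).VEGFR1(L!1)", "VEGFR2(L)"],
          ["VEGF(r!1,r!2).VEGFR1(L!1).VEGFR2(L!2)"], "kc_VR1R2",
          compartments=["PM"], signature=sig)
    )
    rules.append(
        R("dimer_r2r1", ["VEGF(r!1,r).VEGFR2(L!1)", "VEGFR1(L)"],
          ["VEGF(r!1,r!2).VEGFR2(L!1).VEGFR1(L!2)"], "kc_VR1R2",
          compartments=["PM"], signature=sig)
    )

    # --- NRP1 coupling ---
    rules.append(
        R("vegf_nrp1_couple", ["VEGF(nrp1bd,r!+)", "NRP1(l)"],
          ["VEGF(nrp1bd!1,r!+).NRP1(l!1)"], "kVEGFNRP1_on",
          compartments=["PM"], signature=sig)
    )
    rules.append(
        R("vegf_nrp1_uncouple", ["VEGF(nrp1bd!1).NRP1(l!1)"],
          ["VEGF(nrp1bd)", "NRP1(l)"], "kVEGFR2NRP1_off",
          compartments=["PM"], signature=sig)
    )
    rules.append(
        R("r1_nrp1_couple", ["VEGFR1(nrp1bd)", "NRP1(l)"],
          ["VEGFR1(nrp1bd!1).NRP1(l!1)"], "kon_R1NRP1",
          compartments=["PM"], signature=sig)
    )
    rules.append(
        R("r1_nrp1_uncouple", ["VEGFR1(nrp1bd!1).NRP1(l!1)"],
          ["VEGFR1(nrp1bd)", "NRP1(l)"], "koff_R1NRP1",
          compartments=["PM"], signature=sig)
    )

    # --- constitutive VEGFR2-CD47 coupling ---
    rules.append(
        R("r2_cd47_couple", ["VEGFR2(c)", "CD47(vegfr2bd)"],
          ["VEGFR2(c!1).CD47(vegfr2bd!1)"], "kon_R2CD47",
          compartments=["PM"], signature=sig)
    )
    rules.append(
        R("r2_cd47_uncouple", ["VEGFR2(c!1).CD47(vegfr2bd!1)"],
          ["VEGFR2(c)", "CD47(vegfr2bd)"], "koff_R2CD47",
          compartments=["PM"], signature=sig)
    )

    # --- TSP1 binds VEGFR2-coupled CD47 ---
    rules.append(
        R("tsp1_bind", ["TSP1(cd47bd)", "CD47(tsp1bd,vegfr2bd!+)"],
          ["TSP1(cd47bd!1).CD47(tsp1bd!1,vegfr2bd!+)"], "kon_TSP1_CD47",
          compartments=["PM"], signature=sig)
    )
    rules.append(
        R("tsp1_unbind", ["TSP1(cd47bd!1).CD47(tsp1bd!1)"],
          ["TSP1(cd47bd)", "CD47(tsp1bd)"], "koff_TSP1_CD47",
          compartments=["PM"], signature=sig)
    )

    # --- ligand-independent receptor-receptor coupling ---
    rules.append(
        R("rr_couple", ["VEGFR2(c)", "VEGFR2(c)"], ["VEGFR2(c!1).VEGFR2(c!1)"],
          "kc_RR", compartments=["PM"], signature=sig)
    )
    rules.append(
        R("rr_uncouple", ["VEGFR2(c!1).VEGFR2(c!1)"], ["VEGFR2(c)", "VEGFR2(c)"],
          "kd_RR", compartments=["PM"], signature=sig)
    )

    # --- autophosphorylation in VEGF-bridged homodimers ---
    rules.append(
        R("r2_phos",
          ["VEGFR2(L!1,Y1175~u).VEGF(r!1,r!2).VEGFR2(L!2)"],
          ["VEGFR2(L!1,Y1175~p).VEGF(r!1,r!2).VEGFR2(L!2)"],
          "kp_R2", compartments=["PM"], signature=sig)
    )
    # --- dephosphorylation: PM (TSP1 recruits phosphatase), endosomal ---
    rules.append(
        R("r2_dephos_pm", ["VEGFR2(Y1175~p)"], ["VEGFR2(Y1175~u)"], "kdp_s",
          exclude=[(0, _TSP1_BOUND)], compartments=["PM"], signature=sig)
    )
    rules.append(
        R("r2_dephos_pm_tsp1", ["VEGFR2(Y1175~p)"], ["VEGFR2(Y1175~u)"],
          ("kdp_s", "fTSP1_dp"),
          include=[(0, _TSP1_BOUND)], compartments=["PM"], signature=sig)
    )
    rules.append(
        R("r2_dephos_endo", ["VEGFR2(Y1175~p)"], ["VEGFR2(Y1175~u)"], "kdp_i",
          compartments=["SE1", "SE2", "RE"], signature=sig)
    )

    # --- internalization ---
    rules.append(
        R("internalize_dimer",
          ["VEGFR2(L!1).VEGF(r!1,r!2).VEGFR2(L!2)"],
          ["@SE1:VEGFR2(L!1).VEGF(r!1,r!2).VEGFR2(L!2)"],
          "kr2_i", compartments=["PM"], match_once=True, signature=sig)
    )
    rules.append(
        R("internalize_const", ["VEGFR2()"], ["@SE1:VEGFR2()"], "kr2_si",
          compartments=["PM"], match_once=True, signature=sig)
    )
    # --- endosome maturation and NRP1-gated exit to the recycling endosome ---
    rules.append(
        R("se1_to_se2", ["VEGFR2()"], ["@SE2:VEGFR2()"], "kt12",
          compartments=["SE1"], match_once=True, signature=sig)
    )
    rules.append(
        R("se2_to_re", ["VEGFR2()"], ["@RE:VEGFR2()"], "kt2r",
          include=[(0, "NRP1()")], exclude=[(0, _TSP1_BOUND)],
          compartments=["SE2"], match_once=True, signature=sig)
    )
    rules.append(
        R("se2_to_re_tsp1", ["VEGFR2()"], ["@RE:VEGFR2()"], ("kt2r", "fTSP1_i2r"),
          include=[(0, "NRP1()"), (0, _TSP1_BOUND)],
          compartments=["SE2"], match_once=True, signature=sig)
    )
    # --- recycling of unphosphorylated receptors only ---
    rules.append(
        R("recycle", ["VEGFR2()"], ["@PM:VEGFR2()"], "krec",
          exclude=[(0, "VEGFR2(Y1175~p)")],
          compartments=["RE"], match_once=True, signature=sig)
    )

    # --- degradation of VEGFR2 from signaling endosomes ---
    for tag, state, rate in [
        ("deg_p", "p", ("kdeg_i0",)),
        ("deg_p_tsp1", "p", ("kdeg_i0", "fTSP1_deg")),
        ("deg_u", "u", ("kdeg_i0noP",)),
        ("deg_u_tsp1", "u", ("kdeg_i0noP", "fTSP1_deg")),
    ]:
        with_tsp1 = tag.endswith("tsp1")
        rules.append(
            R(tag, [f"VEGFR2(Y1175~{state})"], [], rate,
              include=[(0, _TSP1_BOUND)] if with_tsp1 else (),
              exclude=[] if with_tsp1 else [(0, _TSP1_BOUND)],
              compartments=["SE1", "SE2"], signature=sig)
        )

    # --- ligand dissociation in the recycling endosome ---
    rules.append(
        R("re_vegf_r2_unbind", ["VEGF(r!1).VEGFR2(L!1)"], ["VEGF(r)", "VEGFR2(L)"],
          "kre_off", compartments=["RE"], signature=sig)
    )
    rules.append(
        R("re_vegf_r1_unbind", ["VEGF(r!1).VEGFR1(L!1)"], ["VEGF(r)", "VEGFR1(L)"],
          "kre_off", compartments=["RE"], signature=sig)
    )
    rules.append(
        R("re_vegf_nrp1_unbind", ["VEGF(nrp1bd!1).NRP1(l!1)"],
          ["VEGF(nrp1bd)", "NRP1(l)"], "kre_off", compartments=["RE"], signature=sig)
    )
    rules.append(
        R("re_tsp1_unbind", ["TSP1(cd47bd!1).CD47(tsp1bd!1)"],
          ["TSP1(cd47bd)", "CD47(tsp1bd)"], "kre_off",
          compartments=["RE"], signature=sig)
    )

    # --- free ligand decay inside endosomes ---
    rules.append(
        R("vegf_endo_decay", ["VEGF(r,r,nrp1bd)"], [], "kdeg_ligand_endo",
          compartments=["SE1", "SE2", "RE"], signature=sig)
    )
    rules.append(
        R("tsp1_endo_decay", ["TSP1(cd47bd)"], [], "kdeg_ligand_endo",
          compartments=["SE1", "SE2", "RE"], signature=sig)
    )

    # --- receptor-free partners return to the membrane ---
    for comp in ("SE1", "SE2", "RE"):
        rules.append(
            R(f"return_r1_{comp.lower()}", ["VEGFR1()"], ["@PM:VEGFR1()"],
              "kmisc_rec", exclude=[(0, "VEGFR2()")],
              compartments=[comp], match_once=True, signature=sig)
        )
        rules.append(
            R(f"return_nrp1_{comp.lower()}", ["NRP1()"], ["@PM:NRP1()"],
              "kmisc_rec", exclude=[(0, "VEGFR2()"), (0, "VEGFR1()")],
              compartments=[comp], match_once=True, signature=sig)
        )
        rules.append(
            R(f"return_cd47_{comp.lower()}", ["CD47()"], ["@PM:CD47()"],
              "kmisc_rec", exclude=[(0, "VEGFR2()")],
              compartments=[comp], match_once=True, signature=sig)
        )

    # --- VEGFR2 synthesis at the membrane ---
    rules.append(
        R("r2_synthesis", [], ["@PM:VEGFR2(L,Y1175~u,c)"],
          ("ksingleR2_syn", "R2_total_0"), signature=sig)
    )
    return rules


# ---------------------------------------------------------------------------
# downstream cascade (explicit rate laws)


def calcium_fluxes(state: dict[str, float], params: ParameterSet) -> dict[str, float]:
    """Ca cycling flux terms for d[Ca_cyt]/dt and d[Ca_ER]/dt.

    IP3R release scales with an IP3 Hill function (exponent 3) and the
    ER-cytosol gradient; CRAC entry turns on as the store depletes
    (1 - (Ca_ER/Ca_ER_max)^2, clipped at 0); SERCA is a Hill-2 pump,
    PMCA Hill-1; an ER leak and a constant plasma-membrane influx are
    calibrated so the stated resting point is a steady state.
    """
    ca, ca_er, ip3 = state["Ca"], state["Ca_ER"], state["IP3"]
    if min(ca, ca_er, ip3) < 0:
        raise ValidationError("negative concentration passed to calcium_fluxes")
    p = params
    h = (ip3 / (p["km_ip3"] + ip3)) ** 3
    J_ip3r = p["Iip3R_amp"] * h * (ca_er - ca)
    J_crac = p["ICRAC_amp"] * max(0.0, 1.0 - (ca_er / p["Ca_ER_rest"]) ** 2)
    J_serca = p["v_SERCA"] * ca**2 / (p["km_serca"] ** 2 + ca**2)
    J_pmca = p["IPMCA_amp"] * ca / (p["km_pmca"] + ca)
    # calibrated leaks (resting point is a steady state by construction)
    ca0, caer0 = p["Ca_rest"], p["Ca_ER_rest"]
    ip30 = p["IP3_rest"]
    h0 = (ip30 / (p["km_ip3"] + ip30)) ** 3
    J_serca0 = p["v_SERCA"] * ca0**2 / (p["km_serca"] ** 2 + ca0**2)
    k_erleak = max(0.0, (J_serca0 - p["Iip3R_amp"] * h0 * (caer0 - ca0)) / (caer0 - ca0))
    J_erleak = k_erleak * (ca_er - ca)
    J_in0 = p["IPMCA_amp"] * ca0 / (p["km_pmca"] + ca0)
    return {
        "J_ip3r": J_ip3r,
        "J_crac": J_crac,
        "J_serca": J_serca,
        "J_pmca": J_pmca,
        "J_erleak": J_erleak,
        "J_in": J_in0,
        "dCa": J_ip3r + J_erleak + J_crac + J_in0 - J_serca - J_pmca,
        "dCa_ER": p["beta_er"] * (J_serca - J_ip3r - J_erleak),
    }


class CascadeDynamics:
    """Explicit ODE block for signaling downstream of phosphorylated VEGFR2.

    State (uM): pSrc, pAxl1, pAxl12, aPI3K, PIP3, Akt_m, Akt_mS473, Akt_pp,
    pPLCg, IP3, Ca, Ca_ER, CaCaM, eNOS_cam, eNOS_p.  The single driver is
    the total phosphorylated VEGFR2 over PM+SE1+SE2 (molecules/cell).
    Conserved pools (Axl, PI3K, Akt, PLCg, CaM, eNOS, PIP2+PIP3) are
    represented through their free complements.
    """

    STATE_NAMES = (
        "pSrc", "pAxl1", "pAxl12", "aPI3K", "PIP3",
        "Akt_m", "Akt_mS473", "Akt_pp",
        "pPLCg", "IP3", "Ca", "Ca_ER", "CaCaM", "eNOS_cam", "eNOS_p",
    )
    DRIVERS = ("pR2_signal",)

    def __init__(self, params: ParameterSet):
        self.params = params

    def initial_state(self):
        import numpy as np

        p = self.params
        y = np.zeros(len(self.STATE_NAMES))
        idx = {n: i for i, n in enumerate(self.STATE_NAMES)}
        y[idx["IP3"]] = p["IP3_rest"]
        y[idx["Ca"]] = p["Ca_rest"]
        y[idx["Ca_ER"]] = p["Ca_ER_rest"]
        # resting Ca/CaM equilibrium
        ca = p["Ca_rest"]
        y[idx["CaCaM"]] = (
            p["CaM_0"] * ca**2 / (ca**2 + p["koff_CaCaM"] / p["kon_CaCaM"])
        )
        return y

    def fluxes(self, y, drivers, params: ParameterSet | None = None):
        import numpy as np

        p = params or self.params
        (pSrc, pAxl1, pAxl12, aPI3K, PIP3, Akt_m, Akt_mS473, Akt_pp,
         pPLCg, IP3, Ca, Ca_ER, CaCaM, eNOS_cam, eNOS_p) = [max(v, 0.0) for v in y]
        drive = max(drivers[0], 0.0) + p["drive_basal"]

        dy = np.empty(len(y))
        # TSAd/Src assembly on pR2 is threshold-like (Hill 2): robust above
        # threshold, steeply lost below it
        F_src = drive**2 / (p["km_Src"] ** 2 + drive**2)
        dy[0] = p["kp_Src"] * F_src * (p["Src_0"] - pSrc) - p["kdp_Src"] * pSrc
        axl_free = p["Axl_0"] - pAxl1 - pAxl12
        dy[1] = (p["kp_SrcAxl"] * pSrc * axl_free - p["kdp_SrcAxl"] * pAxl1
                 - p["kp_Axlauto"] * pAxl1 + p["kdp_autoAxl"] * pAxl12)
        dy[2] = p["kp_Axlauto"] * pAxl1 - p["kdp_autoAxl"] * pAxl12
        dy[3] = (p["kon_PI3KAxl"] * pAxl12 * (p["PI3K_0"] - aPI3K)
                 - p["koff_PI3KAxl"] * aPI3K)
        PIP2 = max(p["PIP2_0"] - PIP3, 0.0)
        dy[4] = (p["kcat_PI3KPIP2"] * aPI3K * PIP2 / (p["km_PIP2PI3K"] + PIP2)
                 - p["kcat_PTENPIP3"] * p["PTEN_0"] * PIP3 / (p["km_PIP3PTEN"] + PIP3))
        Akt_c = max(p["Akt_0"] - Akt_m - Akt_mS473 - Akt_pp, 0.0)
        dy[5] = (p["kon_AktPIP3"] * PIP3 * Akt_c - p["koff_Akt"] * Akt_m
                 - p["kp_S473mTOR"] * Akt_m + p["kdp_S473"] * Akt_mS473)
        dy[6] = (p["kp_S473mTOR"] * Akt_m - p["kdp_S473"] * Akt_mS473
                 - p["kp_T308PDK1"] * p["PDK1_0"] * Akt_mS473 + p["kdp_T308"] * Akt_pp)
        dy[7] = p["kp_T308PDK1"] * p["PDK1_0"] * Akt_mS473 - p["kdp_T308"] * Akt_pp
        F_plc = drive / (p["km_PLC"] + drive)
        dy[8] = p["kp_PLC"] * F_plc * (p["PLC_0"] - pPLCg) - p["kdp_PLC"] * pPLCg
        dy[9] = (p["kcat_PLCgDAG"] * pPLCg + p["kdeg_ip3"] * p["IP3_rest"]
                 - p["kdeg_ip3"] * IP3)
        ca_fl = calcium_fluxes({"Ca": Ca, "Ca_ER": Ca_ER, "IP3": IP3}, p)
        dy[10] = ca_fl["dCa"]
        dy[11] = ca_fl["dCa_ER"]
        dy[12] = (p["kon_CaCaM"] * Ca**2 * (p["CaM_0"] - CaCaM)
                  - p["koff_CaCaM"] * CaCaM)
        eNOS_cav = max(p["eNOS_0"] - eNOS_cam - eNOS_p, 0.0)
        dy[13] = (p["kon_eNOSCaCaM"] * CaCaM * eNOS_cav
                  - p["koff_eNOSCaCaM"] * eNOS_cam
                  - p["kp_eNOS"] * Akt_pp * eNOS_cam)
        dy[14] = p["kp_eNOS"] * Akt_pp * eNOS_cam - p["kdp_eNOS"] * eNOS_p
        return dy

    def jacobian(self, y, drivers, params: ParameterSet | None = None):
        """Analytic Jacobian of :meth:`fluxes`: (d f/d y, d f/d drivers)."""
        import numpy as np

        p = params or self.params
        (pSrc, pAxl1, pAxl12, aPI3K, PIP3, Akt_m, Akt_mS473, Akt_pp,
         pPLCg, IP3, Ca, Ca_ER, CaCaM, eNOS_cam, eNOS_p) = [max(v, 0.0) for v in y]
        drive = max(drivers[0], 0.0) + p["drive_basal"]
        n = len(self.STATE_NAMES)
        J = np.zeros((n, n))
        Jd = np.zeros((n, 1))

        km = p["km_Src"]
        F_src = drive**2 / (km**2 + drive**2)
        J[0, 0] = -p["kp_Src"] * F_src - p["kdp_Src"]
        Jd[0, 0] = (p["kp_Src"] * (p["Src_0"] - pSrc)
                    * 2.0 * km**2 * drive / (km**2 + drive**2) ** 2)

        axl_free = p["Axl_0"] - pAxl1 - pAxl12
        J[1, 0] = p["kp_SrcAxl"] * axl_free
        J[1, 1] = -p["kp_SrcAxl"] * pSrc - p["kdp_SrcAxl"] - p["kp_Axlauto"]
        J[1, 2] = -p["kp_SrcAxl"] * pSrc + p["kdp_autoAxl"]
        J[2, 1] = p["kp_Axlauto"]
        J[2, 2] = -p["kdp_autoAxl"]

        J[3, 2] = p["kon_PI3KAxl"] * (p["PI3K_0"] - aPI3K)
        J[3, 3] = -p["kon_PI3KAxl"] * pAxl12 - p["koff_PI3KAxl"]

        pip2_raw = p["PIP2_0"] - PIP3
        PIP2 = max(pip2_raw, 0.0)
        km2, km3 = p["km_PIP2PI3K"], p["km_PIP3PTEN"]
        J[4, 3] = p["kcat_PI3KPIP2"] * PIP2 / (km2 + PIP2)
        dpip2 = (p["kcat_PI3KPIP2"] * aPI3K * km2 / (km2 + PIP2) ** 2
                 if pip2_raw > 0 else 0.0)
        J[4, 4] = -dpip2 - p["kcat_PTENPIP3"] * p["PTEN_0"] * km3 / (km3 + PIP3) ** 2

        aktc_raw = p["Akt_0"] - Akt_m - Akt_mS473 - Akt_pp
        Akt_c = max(aktc_raw, 0.0)
        kon, koff = p["kon_AktPIP3"], p["koff_Akt"]
        kpS, kdpS = p["kp_S473mTOR"], p["kdp_S473"]
        kpT = p["kp_T308PDK1"] * p["PDK1_0"]
        kdpT = p["kdp_T308"]
        kon_c = kon if aktc_raw > 0 else 0.0  # pool-clip consistency
        J[5, 4] = kon * Akt_c
        J[5, 5] = -kon_c * PIP3 - koff - kpS
        J[5, 6] = -kon_c * PIP3 + kdpS
        J[5, 7] = -kon_c * PIP3
        J[6, 5] = kpS
        J[6, 6] = -kdpS - kpT
        J[6, 7] = kdpT
        J[7, 6] = kpT
        J[7, 7] = -kdpT

        kmp = p["km_PLC"]
        F_plc = drive / (kmp + drive)
        J[8, 8] = -p["kp_PLC"] * F_plc - p["kdp_PLC"]
        Jd[8, 0] = p["kp_PLC"] * (p["PLC_0"] - pPLCg) * kmp / (kmp + drive) ** 2

        J[9, 8] = p["kcat_PLCgDAG"]
        J[9, 9] = -p["kdeg_ip3"]

        # calcium block
        kmi = p["km_ip3"]
        h = (IP3 / (kmi + IP3)) ** 3
        dh = 3.0 * (IP3 / (kmi + IP3)) ** 2 * kmi / (kmi + IP3) ** 2
        A = p["Iip3R_amp"]
        grad = Ca_ER - Ca
        ca0, caer0, ip30 = p["Ca_rest"], p["Ca_ER_rest"], p["IP3_rest"]
        h0 = (ip30 / (kmi + ip30)) ** 3
        J_serca0 = p["v_SERCA"] * ca0**2 / (p["km_serca"] ** 2 + ca0**2)
        kl = max(0.0, (J_serca0 - A * h0 * (caer0 - ca0)) / (caer0 - ca0))
        ks = p["km_serca"]
        dJserca = p["v_SERCA"] * 2.0 * ks**2 * Ca / (ks**2 + Ca**2) ** 2
        kp_ = p["km_pmca"]
        dJpmca = p["IPMCA_amp"] * kp_ / (kp_ + Ca) ** 2
        dJcrac = (-2.0 * p["ICRAC_amp"] * Ca_ER / caer0**2
                  if (1.0 - (Ca_ER / caer0) ** 2) > 0 else 0.0)
        J[10, 9] = A * dh * grad
        J[10, 10] = -A * h - kl - dJserca - dJpmca
        J[10, 11] = A * h + kl + dJcrac
        b = p["beta_er"]
        J[11, 9] = -b * A * dh * grad
        J[11, 10] = b * (dJserca + A * h + kl)
        J[11, 11] = -b * (A * h + kl)

        J[12, 10] = 2.0 * p["kon_CaCaM"] * Ca * (p["CaM_0"] - CaCaM)
        J[12, 12] = -p["kon_CaCaM"] * Ca**2 - p["koff_CaCaM"]

        cav_raw = p["eNOS_0"] - eNOS_cam - eNOS_p
        eNOS_cav = max(cav_raw, 0.0)
        kone, koffe = p["kon_eNOSCaCaM"], p["koff_eNOSCaCaM"]
        kpe = p["kp_eNOS"]
        kone_c = kone if cav_raw > 0 else 0.0
        J[13, 7] = -kpe * eNOS_cam
        J[13, 12] = kone * eNOS_cav
        J[13, 13] = -kone_c * CaCaM - koffe - kpe * Akt_pp
        J[13, 14] = -kone_c * CaCaM
        J[14, 7] = kpe * eNOS_cam
        J[14, 13] = kpe * Akt_pp
        J[14, 14] = -p["kdp_eNOS"]
        return J, Jd


def downstream_rules(params: ParameterSet) -> CascadeDynamics:
    """The downstream cascade as an explicit rate-law block (driven by the
    total phosphorylated VEGFR2 on PM + signaling endosomes)."""
    return CascadeDynamics(params)


# ---------------------------------------------------------------------------
# the assembled model


@dataclass
class ModelSpec:
    """Complete model: types, seeds, rules, parameters, initial state."""

    signature: ModelSignature
    seeds: list[SpeciesGraph]
    seed_amounts: dict[str, float]  # canonical label -> amount
    clamped: list[str]  # canonical labels of bath species
    rules: list[RxnRule]
    params: ParameterSet
    init: InitialState
    intervention: InterventionSpec
    cascade: CascadeDynamics
    max_stoich: dict = field(default_factory=lambda: dict(MAX_STOICH))

    def generate(self, **kwargs):
        net = generate_network(
            self.seeds, self.rules, self.signature,
            max_stoich=self.max_stoich, **kwargs,
        )
        return net


def build_model(
    params: ParameterSet | None = None,
    init: InitialState | None = None,
    intervention: InterventionSpec | None = None,
) -> ModelSpec:
    """Assemble the full model under the given parameterization/intervention.

    CD47 depletion scales the CD47 seed amount; an NRP1 knockout zeroes the
    NRP1 seed; CHX zeroes the synthesis rate constant; the TSP1-CD47 Kd
    scale multiplies the TSP1-CD47 off-rate (on-rate fixed); TSP1 depletion
    scales the TSP1 dose applied by the protocol (see experiments module).
    """
    params = (params or nominal_parameters()).copy()
    init = init or InitialState()
    intervention = intervention or InterventionSpec()
    init.validate()
    intervention.validate()
    params.validate()

    if intervention.kd_scale_tsp1cd47 != 1.0:
        params["koff_TSP1_CD47"] *= intervention.kd_scale_tsp1cd47
    if intervention.chx:
        params["ksingleR2_syn"] = 0.0

    sig = signature()
    from .rulegraph import canonical_label

    seed_defs = [
        ("VEGF(r,r,nrp1bd)", init.vegf_nM, True),
        ("TSP1(cd47bd)", init.tsp1_nM, True),
        ("VEGFR2(L,Y1175~u,c)", init.vegfr2_total, False),
        ("VEGFR1(L,nrp1bd,c)", init.vegfr1_total, False),
        ("NRP1(l)", 0.0 if intervention.nrp1_knockout else init.nrp1_total, False),
        ("CD47(vegfr2bd,tsp1bd)",
         init.cd47_total * (1.0 - intervention.cd47_depletion_fraction), False),
    ]
    seeds, seed_amounts, clamped = [], {}, []
    for text, amount, is_bath in seed_defs:
        sp = parse_species(text, sig, "PM")
        label = canonical_label(sp)
        seeds.append(sp)
        seed_amounts[label] = amount
        if is_bath:
            clamped.append(label)

    return ModelSpec(
        signature=sig,
        seeds=seeds,
        seed_amounts=seed_amounts,
        clamped=clamped,
        rules=receptor_rules(sig),
        params=params,
        init=init,
        intervention=intervention,
        cascade=CascadeDynamics(params),
    )
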