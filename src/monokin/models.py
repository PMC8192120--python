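"""Concrete kinetic models of the DAT, NET, and SERT transport cycles.

All three transporters share a sequential-binding core cycle: the
outward-open, Cl⁻-bound transporter binds Na⁺ and then substrate, occludes,
opens inward, releases Na⁺ and then substrate intracellularly. They differ
in how the substrate-free inward-facing transporter returns outward:

* **DAT / NET** — intracellular K⁺ binds the inward-open state (TiClK,
  electrogenic) but is shed again on the way to the occluded state
  (ToccClK → ToccCl, a reduced-affinity site), so K⁺ is never antiported;
  the empty return step (ToccCl → ToCl) carries the transporter's intrinsic
  negative charge outward (zQ = +1 inward-equivalent) and makes the cycle
  voltage-dependent. A direct occlusion path TiCl → ToccCl supports cycling
  without K⁺. DAT and NET share every parameter except substrate binding
  and release kinetics; NET also lacks the conducting state by default.
* **SERT** — K⁺ stays bound through occlusion and is released
  extracellularly (true antiport); the K⁺-loaded return is electroneutral,
  making turnover voltage-independent. An alternative H⁺-antiport branch
  sustains (slower) cycling when intracellular K⁺ is absent. An empty
  electrogenic return also exists but is slow.

A conducting state (Tcond), in equilibrium with the K⁺-bound inward-facing
conformation, carries the uncoupled Na⁺ current where enabled.

Per-edge rate constants are calibrated (see ``scripts/calibrate_models.py``)
against measured catalytic rates and uptake–voltage ratios; Wegscheider
conditions are enforced at build time so every reaction loop is
thermodynamically consistent (zero loop free energy under collapsed
gradients at 0 mV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .scheme import IonConditions, KineticScheme, State, Transition

__all__ = [
    "TransporterModelSpec",
    "build_dat_model",
    "build_net_model",
    "build_sert_model",
    "build_model",
    "get_condition_preset",
    "CONDITION_PRESETS",
    "DAT_PARAMS",
    "NET_PARAMS",
    "SERT_PARAMS",
]


@dataclass
class TransporterModelSpec:
    """A transporter scheme plus the annotations the observables need."""

    transporter_id: str
    scheme: KineticScheme
    params: dict[str, float]
    variants: dict[str, bool] = field(default_factory=dict)
    substrate_bound_inward_state: str = "TiClS"
    inward_empty_state: str = "TiCl"
    conducting_state: str | None = None

    @property
    def substrate_kd(self) -> float:
        return self.params["k_off_S"] / self.params["k_on_S"]


# ---------------------------------------------------------------------------
# Calibrated parameter sets (rates in s⁻¹, bimolecular in M⁻¹·s⁻¹).
# Values marked CAL were fitted by scripts/calibrate_models.py to the
# measured recovery rates and uptake-voltage ratios; the rest are set to
# plausible magnitudes that keep the step well clear of rate limitation.
# ---------------------------------------------------------------------------

_DAT_NET_CORE = {
    # Na+ association from the outside (fast, weak site)
    "k_on_Na": 1.0e6,
    "k_off_Na_out": 6.0e5,
    "z_Na_b": 0.05,
    # occlusion of the fully loaded transporter
    "k_occl_f": 600.0,
    "k_occl_r": 10967.0,  # CAL
    # inward opening (carries part of the co-transported charge)
    "k_open_f": 800.0,
    "k_open_r": 1570.0,
    "z_tr": 0.03,  # CAL
    # Na+ release to the cytosol (low affinity inside: Kd ~125 mM)
    "k_off_Na_in": 2500.0,
    "k_on_Na_in": 2.0e4,
    "z_Na_r": 0.10,
    # charge moved during substrate binding (out) and release (in)
    "z_S_b": 0.10,
    "z_S_r": 0.1377,  # CAL
    # K+ binding to the inward-open state (electrogenic, transient)
    "k_on_K": 1.0e4,
    "k_off_K": 350.38,  # CAL
    "z_K_b": -0.10,
    # occlusion with K+ still bound
    "k_occK_f": 0.3,  # CAL
    "k_occK_r": 5.0,
    # K+ shed intracellularly from the reduced-affinity occluded site
    "k_off_K_occ": 500.0,
    "z_K_r": 0.10,
    # direct occlusion without K+
    "k_occ0_f": 24.271,  # CAL
    "k_occ0_r": 1.0,  # CAL
    # empty return step (rate-limiting, electrogenic)
    "k_ret_f": 2.3239,  # CAL
    "z_ret": 1.0,
    # conducting state in equilibrium with TiClK
    "k_cond_f": 0.8,  # CAL
    "k_cond_r": 1.0e4,
}

DAT_PARAMS = {
    **_DAT_NET_CORE,
    # APP+ kinetics (stated)
    "k_on_S": 9.0e5,
    "k_off_S": 30.0,
    # cognate substrate (dopamine): currents indistinguishable from APP+
    "k_on_S_cognate": 9.0e5,
    "k_off_S_cognate": 30.0,
}

NET_PARAMS = {
    **_DAT_NET_CORE,
    # APP+ kinetics (stated, slower than DAT)
    "k_on_S": 3.0e5,
    "k_off_S": 1.0,
    # cognate substrate (norepinephrine), off-rate CAL for the slow turnover
    "k_on_S_cognate": 3.0e5,
    "k_off_S_cognate": 0.1549,
}

SERT_PARAMS = {
    # Na+ association
    "k_on_Na": 1.0e6,
    "k_off_Na_out": 3.0e5,
    "z_Na_b": 0.05,
    "k_occl_f": 600.0,
    "k_occl_r": 600.0,
    "k_open_f": 800.0,
    "k_open_r": 500.0,
    "z_tr": 0.05,
    "k_off_Na_in": 2000.0,
    "k_on_Na_in": 5.0e4,
    "z_Na_r": 0.15,
    "z_S_b": 0.3564,  # CAL
    "z_S_r": 0.002,  # CAL — shallow voltage dependence of SERT uptake
    # APP+ kinetics (stated)
    "k_on_S": 1.0e5,
    "k_off_S": 1.0,
    # cognate substrate (serotonin)
    "k_on_S_cognate": 1.0e6,
    "k_off_S_cognate": 3.6,
    # K+ antiport branch
    "k_on_K": 1.0e4,
    "k_off_K": 500.0,
    "z_K_b": -0.30,
    "k_occK_f": 66.6,  # CAL
    "k_occK_r": 2.0,
    "k_retK_f": 2.2792,  # CAL — electroneutral K+-loaded return
    "k_retK_r": 1.0,
    "z_retK": 0.0,
    "k_K_rel_out": 1000.0,
    # H+ antiport branch (sustains cycling without K_in+)
    "k_on_H": 1.0e8,  # CAL
    "k_off_H": 20.0,
    "z_H_b": -0.30,
    "k_occH_f": 7.0101,  # CAL
    "k_occH_r": 1.0,
    "k_retH_f": 4.0,
    "k_retH_r": 1.0,
    "k_H_rel_out": 100.0,
    # slow empty electrogenic return
    "k_ret0_f": 0.044,  # CAL
    "z_ret": 1.0,
    # conducting state
    "k_cond_f": 1.0,  # CAL
    "k_cond_r": 1.0e4,
    # Li+ dead-end binding to the inward-open state (variant)
    "k_on_Li": 1.0e4,
    "k_off_Li": 1000.0,
    "z_Li_b": -0.30,
}


def _loop_k_ratio_product(pairs: list[tuple[float, float]]) -> float:
    prod = 1.0
    for kf, kr in pairs:
        prod *= kf / kr
    return prod


def _build_dat_like(
    transporter_id: str,
    params: dict[str, float],
    with_conducting_state: bool,
    cognate: bool,
) -> TransporterModelSpec:
    p = params
    k_on_S = p["k_on_S_cognate"] if cognate else p["k_on_S"]
    k_off_S = p["k_off_S_cognate"] if cognate else p["k_off_S"]

    states = [
        State("ToCl", "outward", {"Cl": 1}),
        State("ToClNa", "outward", {"Cl": 1, "Na": 1}),
        State("ToClNaS", "outward", {"Cl": 1, "Na": 1, "S": 1}),
        State("ToccClNaS", "occluded", {"Cl": 1, "Na": 1, "S": 1}),
        State("TiClNaS", "inward", {"Cl": 1, "Na": 1, "S": 1}),
        State("TiClS", "inward", {"Cl": 1, "S": 1}),
        State("TiCl", "inward", {"Cl": 1}),
        State("TiClK", "inward", {"Cl": 1, "K": 1}),
        State("ToccClK", "occluded", {"Cl": 1, "K": 1}),
        State("ToccCl", "occluded", {"Cl": 1}),
    ]

    # Wegscheider: the reduced-affinity K+ on-rate at the occluded site
    # closes the inner loop TiCl->TiClK->ToccClK->ToccCl->TiCl.
    k_on_K_occ = (
        (p["k_on_K"] / p["k_off_K"])
        * (p["k_occK_f"] / p["k_occK_r"])
        * p["k_off_K_occ"]
        * (p["k_occ0_r"] / p["k_occ0_f"])
    )
    # ...and the return reverse rate closes the outer (transport) loop.
    outer = _loop_k_ratio_product(
        [
            (p["k_on_Na"], p["k_off_Na_out"]),
            (k_on_S, k_off_S),
            (p["k_occl_f"], p["k_occl_r"]),
            (p["k_open_f"], p["k_open_r"]),
            (p["k_off_Na_in"], p["k_on_Na_in"]),
            (k_off_S, k_on_S),
            (p["k_on_K"], p["k_off_K"]),
            (p["k_occK_f"], p["k_occK_r"]),
            (p["k_off_K_occ"], k_on_K_occ),
        ]
    )
    k_ret_r = p["k_ret_f"] * outer

    transitions = [
        Transition("ToCl", "ToClNa", p["k_on_Na"], p["k_off_Na_out"], p["z_Na_b"],
                   ligand_fwd=("Na", "out")),
        Transition("ToClNa", "ToClNaS", k_on_S, k_off_S, p["z_S_b"],
                   ligand_fwd=("S", "out")),
        Transition("ToClNaS", "ToccClNaS", p["k_occl_f"], p["k_occl_r"], 0.0),
        Transition("ToccClNaS", "TiClNaS", p["k_open_f"], p["k_open_r"], p["z_tr"]),
        Transition("TiClNaS", "TiClS", p["k_off_Na_in"], p["k_on_Na_in"], p["z_Na_r"],
                   ligand_rev=("Na", "in")),
        Transition("TiClS", "TiCl", k_off_S, k_on_S, p["z_S_r"],
                   ligand_rev=("S", "in")),
        Transition("TiCl", "TiClK", p["k_on_K"], p["k_off_K"], p["z_K_b"],
                   ligand_fwd=("K", "in")),
        Transition("TiClK", "ToccClK", p["k_occK_f"], p["k_occK_r"], 0.0),
        Transition("ToccClK", "ToccCl", p["k_off_K_occ"], k_on_K_occ, p["z_K_r"],
                   ligand_rev=("K", "in")),
        Transition("TiCl", "ToccCl", p["k_occ0_f"], p["k_occ0_r"], 0.0),
        Transition("ToccCl", "ToCl", p["k_ret_f"], k_ret_r, p["z_ret"]),
    ]

    if with_conducting_state:
        states.append(State("Tcond", "conducting", {"Cl": 1, "K": 1}))
        transitions.append(
            Transition("TiClK", "Tcond", p["k_cond_f"], p["k_cond_r"], 0.0)
        )

    scheme = KineticScheme(
        states=states,
        transitions=transitions,
        metadata={"transporter": transporter_id, "cognate": cognate},
    )
    return TransporterModelSpec(
        transporter_id=transporter_id,
        scheme=scheme,
        params={**p, "k_on_S_active": k_on_S, "k_off_S_active": k_off_S},
        variants={"with_conducting_state": with_conducting_state},
        conducting_state="Tcond" if with_conducting_state else None,
    )


def build_dat_model(
    with_conducting_state: bool = True,
    cognate: bool = False,
    overrides: dict[str, float] | None = None,
    **unknown,
) -> TransporterModelSpec:
    """The dopamine-transporter model (transient intracellular K⁺ binding).

    ``cognate=True`` swaps the default fluorescent-substrate (APP⁺) kinetics
    for the cognate-substrate ones (used by the two-pulse protocol).
    """
    if unknown:
        raise ValueError(f"unknown variant flag(s): {sorted(unknown)}")
    params = {**DAT_PARAMS, **(overrides or {})}
    return _build_dat_like("DAT", params, with_conducting_state, cognate)


def build_net_model(
    with_conducting_state: bool = False,
    cognate: bool = False,
    overrides: dict[str, float] | None = None,
    **unknown,
) -> TransporterModelSpec:
    """The norepinephrine-transporter model: DAT's scheme and parameters with
    slower substrate binding/unbinding and no conducting state by default."""
    if unknown:
        raise ValueError(f"unknown variant flag(s): {sorted(unknown)}")
    params = {**NET_PARAMS, **(overrides or {})}
    return _build_dat_like("NET", params, with_conducting_state, cognate)


def build_sert_model(
    with_conducting_state: bool = True,
    with_proton_branch: bool = True,
    with_li_deadend: bool = False,
    cognate: bool = False,
    overrides: dict[str, float] | None = None,
    **unknown,
) -> TransporterModelSpec:
    """The serotonin-transporter model (K⁺ antiport, H⁺ alternative branch)."""
    if unknown:
        raise ValueError(f"unknown variant flag(s): {sorted(unknown)}")
    p = {**SERT_PARAMS, **(overrides or {})}
    k_on_S = p["k_on_S_cognate"] if cognate else p["k_on_S"]
    k_off_S = p["k_off_S_cognate"] if cognate else p["k_off_S"]

    states = [
        State("ToCl", "outward", {"Cl": 1}),
        State("ToClNa", "outward", {"Cl": 1, "Na": 1}),
        State("ToClNaS", "outward", {"Cl": 1, "Na": 1, "S": 1}),
        State("ToccClNaS", "occluded", {"Cl": 1, "Na": 1, "S": 1}),
        State("TiClNaS", "inward", {"Cl": 1, "Na": 1, "S": 1}),
        State("TiClS", "inward", {"Cl": 1, "S": 1}),
        State("TiCl", "inward", {"Cl": 1}),
        State("TiClK", "inward", {"Cl": 1, "K": 1}),
        State("ToccClK", "occluded", {"Cl": 1, "K": 1}),
        State("ToClK", "outward", {"Cl": 1, "K": 1}),
    ]

    # electroneutral antiport loops: the extracellular release steps carry
    # whatever charge closes the loop to zero net displacement
    core_charge = p["z_Na_b"] + p["z_S_b"] + p["z_tr"] + p["z_Na_r"] + p["z_S_r"]
    z_K_out = -(core_charge + p["z_K_b"] + p["z_retK"])
    z_H_out = -(core_charge + p["z_H_b"])

    core_product = _loop_k_ratio_product(
        [
            (p["k_on_Na"], p["k_off_Na_out"]),
            (k_on_S, k_off_S),
            (p["k_occl_f"], p["k_occl_r"]),
            (p["k_open_f"], p["k_open_r"]),
            (p["k_off_Na_in"], p["k_on_Na_in"]),
            (k_off_S, k_on_S),
        ]
    )
    # K+ antiport loop closes through extracellular K+ rebinding.
    k_branch = _loop_k_ratio_product(
        [
            (p["k_on_K"], p["k_off_K"]),
            (p["k_occK_f"], p["k_occK_r"]),
            (p["k_retK_f"], p["k_retK_r"]),
        ]
    )
    k_on_K_out = core_product * k_branch * p["k_K_rel_out"]
    # Empty electrogenic return closes a loop against the K+ branch.
    k_ret0_r = p["k_ret0_f"] * core_product

    transitions = [
        Transition("ToCl", "ToClNa", p["k_on_Na"], p["k_off_Na_out"], p["z_Na_b"],
                   ligand_fwd=("Na", "out")),
        Transition("ToClNa", "ToClNaS", k_on_S, k_off_S, p["z_S_b"],
                   ligand_fwd=("S", "out")),
        Transition("ToClNaS", "ToccClNaS", p["k_occl_f"], p["k_occl_r"], 0.0),
        Transition("ToccClNaS", "TiClNaS", p["k_open_f"], p["k_open_r"], p["z_tr"]),
        Transition("TiClNaS", "TiClS", p["k_off_Na_in"], p["k_on_Na_in"], p["z_Na_r"],
                   ligand_rev=("Na", "in")),
        Transition("TiClS", "TiCl", k_off_S, k_on_S, p["z_S_r"],
                   ligand_rev=("S", "in")),
        Transition("TiCl", "TiClK", p["k_on_K"], p["k_off_K"], p["z_K_b"],
                   ligand_fwd=("K", "in")),
        Transition("TiClK", "ToccClK", p["k_occK_f"], p["k_occK_r"], 0.0),
        Transition("ToccClK", "ToClK", p["k_retK_f"], p["k_retK_r"], p["z_retK"]),
        Transition("ToClK", "ToCl", p["k_K_rel_out"], k_on_K_out, z_K_out,
                   ligand_rev=("K", "out")),
        Transition("TiCl", "ToCl", p["k_ret0_f"], k_ret0_r, p["z_ret"]),
    ]

    if with_proton_branch:
        states += [
            State("TiClH", "inward", {"Cl": 1, "H": 1}),
            State("ToccClH", "occluded", {"Cl": 1, "H": 1}),
            State("ToClH", "outward", {"Cl": 1, "H": 1}),
        ]
        h_branch = _loop_k_ratio_product(
            [
                (p["k_on_H"], p["k_off_H"]),
                (p["k_occH_f"], p["k_occH_r"]),
                (p["k_retH_f"], p["k_retH_r"]),
            ]
        )
        k_on_H_out = core_product * h_branch * p["k_H_rel_out"]
        transitions += [
            Transition("TiCl", "TiClH", p["k_on_H"], p["k_off_H"], p["z_H_b"],
                       ligand_fwd=("H", "in")),
            Transition("TiClH", "ToccClH", p["k_occH_f"], p["k_occH_r"], 0.0),
            Transition("ToccClH", "ToClH", p["k_retH_f"], p["k_retH_r"], 0.0),
            Transition("ToClH", "ToCl", p["k_H_rel_out"], k_on_H_out, z_H_out,
                       ligand_rev=("H", "out")),
        ]

    if with_li_deadend:
        states.append(State("TiClLi", "inward", {"Cl": 1, "Li": 1}))
        transitions.append(
            Transition("TiCl", "TiClLi", p["k_on_Li"], p["k_off_Li"], p["z_Li_b"],
                       ligand_fwd=("Li", "in"))
        )

    if with_conducting_state:
        states.append(State("Tcond", "conducting", {"Cl": 1, "K": 1}))
        transitions.append(
            Transition("TiClK", "Tcond", p["k_cond_f"], p["k_cond_r"], 0.0)
        )

    scheme = KineticScheme(
        states=states,
        transitions=transitions,
        metadata={"transporter": "SERT", "cognate": cognate},
    )
    return TransporterModelSpec(
        transporter_id="SERT",
        scheme=scheme,
        params={**p, "k_on_S_active": k_on_S, "k_off_S_active": k_off_S},
        variants={
            "with_conducting_state": with_conducting_state,
            "with_proton_branch": with_proton_branch,
            "with_li_deadend": with_li_deadend,
        },
        conducting_state="Tcond" if with_conducting_state else None,
    )


_BUILDERS = {"DAT": build_dat_model, "NET": build_net_model, "SERT": build_sert_model}


def build_model(transporter_id: str, **kwargs) -> TransporterModelSpec:
    """Dispatch to the named transporter builder (DAT, NET, or SERT)."""
    try:
        builder = _BUILDERS[transporter_id.upper()]
    except KeyError:
        raise ValueError(f"unknown transporter {transporter_id!r}") from None
    return builder(**kwargs)


# ---------------------------------------------------------------------------
# Ion-condition presets: external solution is always Na+-based (163 mM NaCl);
# internal solutions follow the patch-pipette recipes.
# ---------------------------------------------------------------------------

_EXTERNAL = dict(Na_out=0.163, Cl_out=0.170, pH_out=7.4)

CONDITION_PRESETS: dict[str, IonConditions] = {
    # 133 mM K-gluconate + KOH titration: final K_in+ 163 mM, Na_in+ 6 mM
    "physiological": IonConditions.build(
        **_EXTERNAL, K_in=0.163, Na_in=0.006, Cl_in=0.009, pH_in=7.2
    ),
    # Na_in+/K_in+ replaced by the inert cation NMDG+
    "NMDG_in": IonConditions.build(**_EXTERNAL, Cl_in=0.163, pH_in=7.2),
    # K-gluconate replaced by NaCl: 163 mM Na_in+
    "high_Na_in": IonConditions.build(
        **_EXTERNAL, Na_in=0.163, Cl_in=0.166, pH_in=7.2
    ),
    # K-gluconate replaced by LiCl: 163 mM Li_in+
    "high_Li_in": IonConditions.build(
        **_EXTERNAL, Li_in=0.163, Cl_in=0.139, pH_in=7.2
    ),
    # acidic internal solution (NMDG-based, pH 5.6)
    "pH5.6_in": IonConditions.build(**_EXTERNAL, Cl_in=0.140, pH_in=5.6),
    # bath solution on both sides (control)
    "control_external": IonConditions.build(
        **_EXTERNAL, Na_in=0.163, Cl_in=0.170, pH_in=7.4
    ),
}


def get_condition_preset(name: str) -> IonConditions:
    """Named intracellular/extracellular solution pairs used by the protocols."""
    try:
        return CONDITION_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown condition preset {name!r}; choose from {sorted(CONDITION_PRESETS)}"
        ) from None
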