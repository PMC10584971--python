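{
  "fresh.oocyte_pickup": "Fresh cycle — Oocyte pick up",
  "fresh.usable_oocytes": "Fresh cycle — Oocytes after pick up",
  "fresh.icsi_share": "Fresh cycle — IVF versus ICSI (interpreted as the probability that ICSI is performed)",
  "fresh.ivf_fertilization": "Fresh cycle — Fertilization after IVF",
  "fresh.ivf_transfer": "Fresh cycle — Embryo transfer after IVF fertilization",
  "fresh.ivf_pregnancy": "Fresh cycle — Pregnancy after IVF embryo transfer",
  "fresh.icsi_fertilization": "Fresh cycle — Fertilization after ICSI",
  "fresh.icsi_transfer": "Fresh cycle — Embryo transfer after ICSI fertilization",
  "fresh.icsi_pregnancy": "Fresh cycle — Pregnancy after ICSI embryo transfer",
  "frozen.embryo_survival": "Frozen cycle — Survival frozen embryo",
  "frozen.pregnancy_after_survival": "Frozen cycle — Clinical pregnancy after survived embryo",
  "sequence.start_cycle2_after_failure": "Up to 3 cycles sequence — Initiating 2nd cycle after failure of 1st cycle",
  "sequence.fresh_share_cycle2": "Up to 3 cycles sequence — Fresh cycle at 2nd cycle versus frozen cycle",
  "sequence.start_cycle3_after_failure": "Up to 3 cycles sequence — Initiating 3rd cycle after failure of 2nd cycle",
  "sequence.fresh_share_cycle3": "Up to 3 cycles sequence — Fresh cycle at 3rd cycle versus frozen cycle",
  "cost.stim_rfsh": "Costs — rFSH stimulation treatment",
  "cost.stim_rfsh_myoins": "Costs — rFSH + inositol stimulation treatment",
  "cost.other_hormones": "Costs — Other hormones (GnRHa, hCG)",
  "cost.monitoring_ultrasounds": "Costs — Monitoring ultrasounds",
  "cost.consultations": "Costs — Consultations",
  "cost.oocyte_pickup": "Costs — Oocyte pickup",
  "cost.pickup_ultrasound": "Costs — Oocyte pickup ultrasound (single printed value, fixed at €30)",
  "cost.ivf_lab": "Costs — IVF laboratory",
  "cost.fresh_et_ivf_catheter": "Costs — Fresh embryo transfer after IVF, catheter + disposables",
  "cost.ohss_treatment": "Costs — OHSS treatment (not billed by default; see ohss_prob)",
  "cost.icsi_procedure": "Costs — ICSI procedure",
  "cost.icsi_lab": "Costs — ICSI laboratory",
  "cost.icsi_et_catheter": "Costs — Embryo transfer after ICSI, catheter + disposables",
  "cost.freeze_and_thaw": "Costs — Frozen embryo and thawing",
  "cost.frozen_et_catheter": "Costs — Frozen embryo transfer, catheter + disposables"
}
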