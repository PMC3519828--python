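generated_by: gemkin calibration pipeline (cascade fit + full-network refinement with
  global pre-search)
objective: 1.5444
rates:
  deam_dFdC: 0.000896264408
  deam_dFdC_MP: 0.03002571244
  dephos_dFdC_DP: 0.1670419313
  dephos_dFdC_MP: 1.822458838
  dephos_dFdC_TP: 33.18546309
  dephos_dFdU_MP: 4.305297142e-07
  efflux_dFdC: 0.07727795313
  efflux_dFdU: 0.06362012074
  incorp_dCTP: 0.1953542304
  incorp_dFdC_TP: 0.07381656505
  incorp_dFdU_TP: 0.4879821801
  influx_dFdC: 89.62404289
  ka_dck: 0.000227348907
  ka_dcmpd: 3.163623803e-10
  ka_rr: 1.326990859e-07
  kd_dck: 0.4851033637
  kd_dcmpd: 1.0
  phos_dFdC: 501.1837805
  phos_dFdC_DP: 46.5383355
  phos_dFdC_MP: 1.570152765
  phos_dFdU: 1.419175627
  phos_dFdU_DP: 1.202914442
  phos_dFdU_MP: 0.4671243734
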