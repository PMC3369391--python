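# Baseline physiology for a pregnant woman (first trimester) and her fetus.
# Units: volumes mL, plasma flows mL/min, partition ratios dimensionless,
# renal clearance mL/min, lithium content mEq per mg of lithium carbonate.
plasma_volume_ml: 5200.0
renal_clearance_ml_min: 20.0
li_meq_per_mg: 0.02666666666666667
compartments:
  brain:
    volume_ml: 1450.0
    flow_ml_min: 700.0
    partition: 1.5
  thyroid:
    volume_ml: 13.0
    flow_ml_min: 60.0
    partition: 1.5
  bone:
    volume_ml: 7273.0
    flow_ml_min: 272.0
    partition: 1.5
  gi_tract:
    volume_ml: 1650.0
    flow_ml_min: 1100.0
    partition: 1.0
  kidney:
    volume_ml: 280.0
    flow_ml_min: 1240.0
    partition: 1.0
  uterus:
    volume_ml: 1000.0
    flow_ml_min: 475.0
    partition: 0.4
  fetus:
    volume_ml: 150.0
    flow_ml_min: 300.0
    partition: 0.8
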