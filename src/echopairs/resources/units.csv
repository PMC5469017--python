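# unit_id,dimension,surface_variants(;-separated)
percent,percent,%;percent;pct
mm,length_mm,mm;millimeter;millimeters
cm,length_cm,cm;centimeter;centimeters
cm2,area_cm2,cm2;cm^2;sq cm;square centimeters
m_s,velocity_m_s,m/s;m/sec;meters per second
cm_s,velocity_cm_s,cm/s;cm/sec
mmhg,pressure_mmHg,mmhg;mm hg
dimensionless,dimensionless,
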