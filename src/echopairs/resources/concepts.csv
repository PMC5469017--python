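# concept_id,label,value_kind,compatible_units,anatomy_tags,measure_tags
left_ventricular_ejection_fraction,Left ventricular ejection fraction,BOTH,percent,left;ventricle,fraction
left_ventricular_dimension_end_diastole,Left ventricular dimension at end diastole,QUANTITATIVE,mm;cm,left;ventricle,dimension;diastole
left_ventricular_dimension_end_systole,Left ventricular dimension at end systole,QUANTITATIVE,mm;cm,left;ventricle,dimension;systole
left_ventricular_size,Left ventricular size,BOTH,mm;cm,left;ventricle,size
left_ventricular_hypertrophy,Left ventricular hypertrophy,QUALITATIVE,,left;ventricle,hypertrophy
left_ventricular_contractility,Left ventricular contractility,QUALITATIVE,,left;ventricle,contractility
left_ventricular_posterior_wall_thickness_end_diastole,Left ventricular posterior wall thickness at end diastole,QUANTITATIVE,mm;cm,left;ventricle;posterior_wall,dimension;diastole
interventricular_septum_dimension_end_diastole,Interventricular septum dimension at end diastole,QUANTITATIVE,mm;cm,septum,dimension;diastole
left_atrium_size_end_systole,Left atrium size at end systole,BOTH,mm;cm,left;atrium,size;dimension;systole
e_e_prime_ratio,E/e' ratio,QUANTITATIVE,dimensionless,,ratio
aortic_valve_max_pressure_gradient,Aortic valve max pressure gradient,QUANTITATIVE,mmhg,aortic;valve,pressure;gradient;extremum
aortic_valve_mean_pressure_gradient,Aortic valve mean pressure gradient,QUANTITATIVE,mmhg,aortic;valve,pressure;gradient;mean
aortic_valve_orifice_area,Aortic valve orifice area,QUANTITATIVE,cm2,aortic;valve,area
aortic_valve_regurgitation,Aortic valve regurgitation,QUALITATIVE,,aortic;valve,regurgitation
aortic_valve_regurgitation_peak_velocity,Aortic valve regurgitation peak velocity,QUANTITATIVE,m_s;cm_s,aortic;valve,regurgitation;velocity;extremum
aortic_valve_stenosis,Aortic valve stenosis,QUALITATIVE,,aortic;valve,stenosis
mitral_valve_mean_pressure_gradient,Mitral valve mean pressure gradient,QUANTITATIVE,mmhg,mitral;valve,pressure;gradient;mean
mitral_valve_orifice_area,Mitral valve orifice area,QUANTITATIVE,cm2,mitral;valve,area
mitral_valve_regurgitation,Mitral valve regurgitation,QUALITATIVE,,mitral;valve,regurgitation
mitral_valve_regurgitation_peak_velocity,Mitral valve regurgitation peak velocity,QUANTITATIVE,m_s;cm_s,mitral;valve,regurgitation;velocity;extremum
mitral_valve_stenosis,Mitral valve stenosis,QUALITATIVE,,mitral;valve,stenosis
pulmonary_artery_pressure,Pulmonary artery pressure,QUANTITATIVE,mmhg,pulmonary,pressure
right_atrial_pressure,Right atrial pressure,QUANTITATIVE,mmhg,right;atrium,pressure
tricuspid_valve_mean_pressure_gradient,Tricuspid valve mean pressure gradient,QUANTITATIVE,mmhg,tricuspid;valve,pressure;gradient;mean
tricuspid_valve_regurgitation,Tricuspid valve regurgitation,QUALITATIVE,,tricuspid;valve,regurgitation
tricuspid_valve_regurgitation_peak_velocity,Tricuspid valve regurgitation peak velocity,QUANTITATIVE,m_s;cm_s,tricuspid;valve,regurgitation;velocity;extremum
tricuspid_valve_orifice_area,Tricuspid valve orifice area,QUANTITATIVE,cm2,tricuspid;valve,area
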