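# term,concept_id  (one pair per line; surfaces are normalized on load)
left ventricular ejection fraction,left_ventricular_ejection_fraction
left ventricle ejection fraction,left_ventricular_ejection_fraction
lv ejection fraction,left_ventricular_ejection_fraction
ejection fraction,left_ventricular_ejection_fraction
edjection fraction,left_ventricular_ejection_fraction
ef,left_ventricular_ejection_fraction
lvef,left_ventricular_ejection_fraction
lv ef,left_ventricular_ejection_fraction
lv ej frac,left_ventricular_ejection_fraction
left ventricular end diastolic dimension,left_ventricular_dimension_end_diastole
left ventricular dimension at end diastole,left_ventricular_dimension_end_diastole
left ventricular diastolic dimension,left_ventricular_dimension_end_diastole
left ventricular end diastolic diameter,left_ventricular_dimension_end_diastole
lvedd,left_ventricular_dimension_end_diastole
lved,left_ventricular_dimension_end_diastole
lvidd,left_ventricular_dimension_end_diastole
lvid d,left_ventricular_dimension_end_diastole
lvd ed,left_ventricular_dimension_end_diastole
left ventricular end systolic dimension,left_ventricular_dimension_end_systole
left ventricular dimension at end systole,left_ventricular_dimension_end_systole
left ventricular systolic dimension,left_ventricular_dimension_end_systole
left ventricular end systolic diameter,left_ventricular_dimension_end_systole
lvesd,left_ventricular_dimension_end_systole
lvids,left_ventricular_dimension_end_systole
lvid s,left_ventricular_dimension_end_systole
lvd es,left_ventricular_dimension_end_systole
left ventricular size,left_ventricular_size
left ventricle size,left_ventricular_size
lv size,left_ventricular_size
left ventricular cavity size,left_ventricular_size
left ventricular hypertrophy,left_ventricular_hypertrophy
lv hypertrophy,left_ventricular_hypertrophy
lvh,left_ventricular_hypertrophy
left ventricular contractility,left_ventricular_contractility
lv contractility,left_ventricular_contractility
left ventricular systolic function,left_ventricular_contractility
lv systolic function,left_ventricular_contractility
left ventricular posterior wall thickness at end diastole,left_ventricular_posterior_wall_thickness_end_diastole
left ventricular posterior wall thickness,left_ventricular_posterior_wall_thickness_end_diastole
posterior wall thickness,left_ventricular_posterior_wall_thickness_end_diastole
lvpwd,left_ventricular_posterior_wall_thickness_end_diastole
lvpw,left_ventricular_posterior_wall_thickness_end_diastole
interventricular septum dimension at end diastole,interventricular_septum_dimension_end_diastole
interventricular septal thickness,interventricular_septum_dimension_end_diastole
interventricular septum thickness,interventricular_septum_dimension_end_diastole
septal thickness,interventricular_septum_dimension_end_diastole
ivsd,interventricular_septum_dimension_end_diastole
ivs,interventricular_septum_dimension_end_diastole
left atrium size at end systole,left_atrium_size_end_systole
left atrial size,left_atrium_size_end_systole
left atrium size,left_atrium_size_end_systole
la size,left_atrium_size_end_systole
left atrial diameter,left_atrium_size_end_systole
left atrium diameter,left_atrium_size_end_systole
la diameter,left_atrium_size_end_systole
la dimension,left_atrium_size_end_systole
e/e' ratio,e_e_prime_ratio
e/e',e_e_prime_ratio
e/e prime,e_e_prime_ratio
e/e ratio,e_e_prime_ratio
e to e prime,e_e_prime_ratio
e to e prime ratio,e_e_prime_ratio
aortic valve max pressure gradient,aortic_valve_max_pressure_gradient
aortic valve maximum pressure gradient,aortic_valve_max_pressure_gradient
aortic valve peak pressure gradient,aortic_valve_max_pressure_gradient
aortic valve peak gradient,aortic_valve_max_pressure_gradient
av max pg,aortic_valve_max_pressure_gradient
av peak gradient,aortic_valve_max_pressure_gradient
aortic valve mean pressure gradient,aortic_valve_mean_pressure_gradient
aortic valve mean gradient,aortic_valve_mean_pressure_gradient
av mean pg,aortic_valve_mean_pressure_gradient
av mean gradient,aortic_valve_mean_pressure_gradient
aortic valve orifice area,aortic_valve_orifice_area
aortic valve area,aortic_valve_orifice_area
av area,aortic_valve_orifice_area
ava,aortic_valve_orifice_area
aortic valve regurgitation,aortic_valve_regurgitation
aortic regurgitation,aortic_valve_regurgitation
aortic insufficiency,aortic_valve_regurgitation
aortic valve insufficiency,aortic_valve_regurgitation
ar,aortic_valve_regurgitation
aortic valve regurgitation peak velocity,aortic_valve_regurgitation_peak_velocity
aortic regurgitation peak velocity,aortic_valve_regurgitation_peak_velocity
ar peak velocity,aortic_valve_regurgitation_peak_velocity
ar vmax,aortic_valve_regurgitation_peak_velocity
aortic valve stenosis,aortic_valve_stenosis
aortic stenosis,aortic_valve_stenosis
mitral valve mean pressure gradient,mitral_valve_mean_pressure_gradient
mitral valve mean gradient,mitral_valve_mean_pressure_gradient
mitral mean gradient,mitral_valve_mean_pressure_gradient
mv mean pg,mitral_valve_mean_pressure_gradient
mitral valve orifice area,mitral_valve_orifice_area
mitral valve area,mitral_valve_orifice_area
mv area,mitral_valve_orifice_area
mva,mitral_valve_orifice_area
mitral valve regurgitation,mitral_valve_regurgitation
mitral regurgitation,mitral_valve_regurgitation
mitral insufficiency,mitral_valve_regurgitation
mitral valve insufficiency,mitral_valve_regurgitation
mr,mitral_valve_regurgitation
mitral valve regurgitation peak velocity,mitral_valve_regurgitation_peak_velocity
mitral regurgitation peak velocity,mitral_valve_regurgitation_peak_velocity
mr peak velocity,mitral_valve_regurgitation_peak_velocity
mr vmax,mitral_valve_regurgitation_peak_velocity
mitral valve stenosis,mitral_valve_stenosis
mitral stenosis,mitral_valve_stenosis
pulmonary artery pressure,pulmonary_artery_pressure
pulmonary artery systolic pressure,pulmonary_artery_pressure
pa pressure,pulmonary_artery_pressure
pa systolic pressure,pulmonary_artery_pressure
pasp,pulmonary_artery_pressure
right atrial pressure,right_atrial_pressure
right atrium pressure,right_atrial_pressure
ra pressure,right_atrial_pressure
rap,right_atrial_pressure
tricuspid valve mean pressure gradient,tricuspid_valve_mean_pressure_gradient
tricuspid valve mean gradient,tricuspid_valve_mean_pressure_gradient
tv mean pg,tricuspid_valve_mean_pressure_gradient
tricuspid valve regurgitation,tricuspid_valve_regurgitation
tricuspid regurgitation,tricuspid_valve_regurgitation
tricuspid insufficiency,tricuspid_valve_regurgitation
tr,tricuspid_valve_regurgitation
tricuspid valve regurgitation peak velocity,tricuspid_valve_regurgitation_peak_velocity
tricuspid regurgitation peak velocity,tricuspid_valve_regurgitation_peak_velocity
tricuspid regurgitation jet velocity,tricuspid_valve_regurgitation_peak_velocity
tricuspid regurgitation jet peak velocity,tricuspid_valve_regurgitation_peak_velocity
tr jet velocity,tricuspid_valve_regurgitation_peak_velocity
tr peak velocity,tricuspid_valve_regurgitation_peak_velocity
tr vmax,tricuspid_valve_regurgitation_peak_velocity
tricuspid valve orifice area,tricuspid_valve_orifice_area
tricuspid valve area,tricuspid_valve_orifice_area
tv area,tricuspid_valve_orifice_area
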