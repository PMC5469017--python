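# surface,category,group_id
# Single words with a semantic category; variants and misspellings of one
# word share a group so constraint rules fire uniformly.
left,ANATOMY,left
lt,ANATOMY,left
right,ANATOMY,right
rt,ANATOMY,right
ventricular,ANATOMY,ventricle
ventricle,ANATOMY,ventricle
ventrical,ANATOMY,ventricle
atrial,ANATOMY,atrium
atrium,ANATOMY,atrium
atria,ANATOMY,atrium
mitral,ANATOMY,mitral
tricuspid,ANATOMY,tricuspid
aortic,ANATOMY,aortic
aorta,ANATOMY,aortic
pulmonary,ANATOMY,pulmonary
pulmonic,ANATOMY,pulmonary
artery,ANATOMY,artery
septum,ANATOMY,septum
septal,ANATOMY,septum
interventricular,ANATOMY,septum
posterior,ANATOMY,posterior_wall
wall,ANATOMY,posterior_wall
valve,ANATOMY,valve
valvular,ANATOMY,valve
dimension,MEASURE,dimension
dimensions,MEASURE,dimension
diameter,MEASURE,dimension
thickness,MEASURE,dimension
area,MEASURE,area
volume,MEASURE,volume
volumes,MEASURE,volume
velocity,MEASURE,velocity
jet,MEASURE,velocity
pressure,MEASURE,pressure
pressures,MEASURE,pressure
gradient,MEASURE,gradient
fraction,MEASURE,fraction
ejection,MEASURE,fraction
ratio,MEASURE,ratio
regurgitation,MEASURE,regurgitation
regurgitant,MEASURE,regurgitation
insufficiency,MEASURE,regurgitation
stenosis,MEASURE,stenosis
stenotic,MEASURE,stenosis
hypertrophy,MEASURE,hypertrophy
contractility,MEASURE,contractility
size,MEASURE,size
diastolic,MEASURE,diastole
diastole,MEASURE,diastole
systolic,MEASURE,systole
systole,MEASURE,systole
end,MEASURE,phase
peak,MEASURE,extremum
max,MEASURE,extremum
maximum,MEASURE,extremum
mean,MEASURE,mean
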