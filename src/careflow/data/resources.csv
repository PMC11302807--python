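id,name,category,annual_cost,annual_days,daily_hours,ccr,useful_life_years
therapist,Radiation therapist,personnel,,260,8,0.71,
cma,Certified medical assistant,personnel,,260,8,0.32,
nurse,Nurse,personnel,,260,8,0.64,
physicist,Medical physicist,personnel,,260,8,2.34,
attending,Attending physician,personnel,,260,8,4.40,
dosimetrist,Dosimetrist,personnel,,260,8,1.14,
resident,MP & MD residents,personnel,,260,8,0.59,
truebeam_vault,TrueBeam vault,space,,260,10,0.31,25
mridian_vault,MRIdian vault,space,,260,10,0.36,25
petct_room,PET/CT room,space,,260,8,0.08,25
truebeam,TrueBeam,equipment,,260,10,4.04,10
mridian,MRIdian,equipment,,260,10,8.01,10
petct_sim,Cannon PET/CT simulator,equipment,,260,8,3.21,10
identify,Identify surface imaging,equipment,,260,10,0.47,10
orfit,Orfit SBRT solution,equipment,,260,10,0.05,10
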