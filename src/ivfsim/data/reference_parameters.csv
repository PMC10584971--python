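block,name,arm,min,max,units
fresh,oocyte_pickup,rfsh_myoins,70,80,pct
fresh,usable_oocytes,rfsh_myoins,85,95,pct
fresh,icsi_share,rfsh_myoins,10,50,pct
fresh,ivf_fertilization,rfsh_myoins,35,75,pct
fresh,ivf_transfer,rfsh_myoins,75,95,pct
fresh,ivf_pregnancy,rfsh_myoins,20,45,pct
fresh,icsi_fertilization,rfsh_myoins,85,100,pct
fresh,icsi_transfer,rfsh_myoins,85,100,pct
fresh,icsi_pregnancy,rfsh_myoins,20,45,pct
fresh,oocyte_pickup,rfsh,70,80,pct
fresh,usable_oocytes,rfsh,80,90,pct
fresh,icsi_share,rfsh,10,50,pct
fresh,ivf_fertilization,rfsh,30,70,pct
fresh,ivf_transfer,rfsh,70,90,pct
fresh,ivf_pregnancy,rfsh,20,45,pct
fresh,icsi_fertilization,rfsh,80,100,pct
fresh,icsi_transfer,rfsh,80,100,pct
fresh,icsi_pregnancy,rfsh,20,45,pct
frozen,embryo_survival,shared,90,100,pct
frozen,pregnancy_after_survival,shared,20,45,pct
sequence,start_cycle2_after_failure,shared,70,100,pct
sequence,fresh_share_cycle2,shared,40,60,pct
sequence,start_cycle3_after_failure,shared,30,60,pct
sequence,fresh_share_cycle3,shared,20,30,pct
cost,stim_rfsh,shared,1000,2000,eur
cost,stim_rfsh_myoins,shared,900,1900,eur
cost,other_hormones,shared,40,360,eur
cost,monitoring_ultrasounds,shared,90,200,eur
cost,consultations,shared,60,200,eur
cost,oocyte_pickup,shared,1000,1000,eur
cost,pickup_ultrasound,shared,30,30,eur
cost,ivf_lab,shared,300,600,eur
cost,fresh_et_ivf_catheter,shared,100,200,eur
cost,ohss_treatment,shared,90,150,eur
cost,icsi_procedure,shared,500,700,eur
cost,icsi_lab,shared,300,700,eur
cost,icsi_et_catheter,shared,100,200,eur
cost,freeze_and_thaw,shared,150,500,eur
cost,frozen_et_catheter,shared,100,200,eur
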