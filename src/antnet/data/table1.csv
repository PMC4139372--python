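ant,Stryphnodendron adstringens,Stryphnodendron polyphyllum,Qualea grandiflora,Ouratea hexasperma,Qualea parviflora,Qualea multiflora,Ouratea spectabilis,Caryocar brasiliense,Lafoensia pacari
Brachymyrmex sp.1,3,7,5,8,4,10,2,9,5
Camponotus sp.1,1,0,2,1,0,0,0,0,0
Camponotus crassus,15,18,17,12,19,20,15,16,20
Camponotus blandus,5,8,5,10,4,2,9,6,6
Camponotus trapeziceps,1,2,1,3,3,5,2,2,0
Camponotus leydigi,1,1,0,3,0,0,0,1,0
Camponotus lespesii,1,0,0,0,0,1,0,0,0
Camponotus vittatus,0,0,0,0,2,1,0,0,0
Crematogaster erecta,1,2,2,2,1,0,3,5,0
Crematogaster bruchi,1,1,2,1,3,1,1,0,0
Pheidole sp.1,1,1,1,0,0,1,1,0,1
Pheidole sp.2,0,2,1,1,1,0,0,0,0
Solenopsis sp.1,0,2,3,1,0,0,3,2,1
Solenopsis sp.2,0,0,1,1,1,0,4,0,1
Cephalotes sp.1,1,0,0,0,0,0,0,0,0
Cephalotes pusillus,10,17,16,13,17,11,15,17,6
Cephalotes bruchi,0,1,0,0,0,0,0,0,1
Cephalotes atratus,1,0,0,0,0,0,0,0,0
Nesomyrmex spininodis,2,0,1,2,1,0,0,3,0
Azteca sp.1,2,6,1,3,4,2,0,5,4
Linepithema aztecoides,0,0,0,0,0,0,0,1,0
Forelius brasiliensis,0,0,0,0,0,1,0,0,0
Pseudomyrmex sp.1,0,1,1,0,0,1,0,0,0
Pseudomyrmex sp.2,0,0,0,0,0,0,1,0,0
Pseudomyrmex gracilis,4,9,13,5,3,9,7,10,3
Pseudomyrmex flavidulus,6,14,4,5,3,5,5,18,1
Gnamptogenys semiferox,0,1,0,0,1,0,1,0,0
Ectatomma tuberculatum,9,4,7,5,2,6,1,1,1
Ectatomma edentatum,0,0,0,0,0,2,0,0,0
Ectatomma planidens,0,0,0,1,0,0,1,0,0
Pachycondyla villosa,1,1,3,0,1,0,0,0,1
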