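genus,species,cutting_preference,in_phylogeny,refs
Acromyrmex,ambiguus,Dicot,Included,"1,2,3,8"
Acromyrmex,ameliae,?,Included,
Acromyrmex,aspersus,Dicot,Included,"2,3"
Acromyrmex,balzani,Grass,Included,"1,2,4,3,5"
Acromyrmex,coronatus,Dicot,Included,"1,2,3,4"
Acromyrmex,crassispinus,Dicot,Included,"2,3,8"
Acromyrmex,diasi,Dicot?-Grass,,"2,3"
Acromyrmex,disciger,Dicot,Included,"1,2,3"
Acromyrmex,evenkul,?,,
Acromyrmex,fracticornis,Grass,Included,"1,3,5,8"
Acromyrmex,heyeri,Grass,Included,"2,3,8"
Acromyrmex,hispidus,Dicot,Included,"1,2,3,8"
Acromyrmex,hystrix,Dicot,,"1,2,3"
Acromyrmex,landolti,Grass,Included,"1,2,3,4,5,8"
Acromyrmex,laticeps,Dicot,Included,"1,2,3,8"
Acromyrmex,lobicornis,Dicot-Grass,Included,"2,3,6,8"
Acromyrmex,lundii,Dicot,Included,"1,2,3,8"
Acromyrmex,molestans,Dicot?,,
Acromyrmex,niger,Dicot,Included,"1,2,3"
Acromyrmex,nigrosetosus,Dicot,Included,1
Acromyrmex,nobilis,Dicot,,"2,3"
Acromyrmex,octospinosus,Dicot,Included,"1,2,3,4"
Acromyrmex,pubescens,?,,
Acromyrmex,pulvereus,Grass,,"2,3"
Acromyrmex,rugosus,Dicot,Included,"1,2,3,4"
Acromyrmex,santschii,Dicot?,,
Acromyrmex,subterraneus,Dicot,Included,"1,2,3,8"
Acromyrmex,versicolor,Dicot,Included,"2,3"
Amoimyrmex,bruchi,Grass?,Included,
Amoimyrmex,silvestrii,Grass,Included,"2,3,8"
Amoimyrmex,striatus,Grass,Included,"2,3,8"
Atta,bisphaerica,Grass,Included,"2,3,4"
Atta,capiguara,Grass,,"2,3,4"
Atta,cephalotes,Dicot,Included,"2,3,4,8"
Atta,colombica,Dicot,Included,"2,3,4"
Atta,cubana,Dicot?,,
Atta,goiana,Grass,,"2,3"
Atta,insularis,Dicot,,"2,3,4"
Atta,laevigata,Dicot-Grass,Included,"2,3,4"
Atta,mexicana,Dicot-Grass,Included,"2,3,4"
Atta,opaciceps,Dicot,Included,"2,3"
Atta,robusta,Dicot,Included,"2,3"
Atta,saltensis,Dicot,Included,"3,8"
Atta,sexdens,Dicot,Included,"2,3,4,8"
Atta,texana,Dicot,Included,"2,3,4"
Atta,vollenweideri,Grass,Included,"2,3,4,7,8"
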