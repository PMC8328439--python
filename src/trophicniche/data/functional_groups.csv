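taxon,family,group
Pleuronectes platessa/Platichthys flesus,Pleuronectidae,benthic flatfish
Solea solea/Pegusa lascaris,Soleidae,benthic flatfish
Buglossidium luteum/Microchirus variegatus,Soleidae,benthic flatfish
Und. Bothidae,Bothidae,benthic flatfish
Scophtalmus spp.,Bothidae,benthic flatfish
Phrynorhombus norvegicus,Bothidae,benthic flatfish
Und. Gobidae,Gobidae,benthic non-flatfish
Trachinus draco,Trachinidae,benthic non-flatfish
Callionymus lyra,Callionymidae,benthic non-flatfish
Und. Triglidae,Triglidae,benthic non-flatfish
Merlangius merlangus,Gadidae,demersal fish
Trisopterus spp.,Gadidae,demersal fish
Gadus morhua/Pollachius spp./Melanogrammus aeglefinus,Gadidae,demersal fish
Und. Sandeels,Ammodytidae,demersal fish
Dicentrarchus labrax,Moronidae,demersal fish
Und. Mullets,Mugilidae,demersal fish
Clupea harengus,Clupeidae,pelagic fish
Sardina pilchardus,Clupeidae,pelagic fish
Sprattus sprattus,Clupeidae,pelagic fish
Belone belone,Belonidae,pelagic fish
Trachurus trachurus,Carangidae,pelagic fish
Loligo spp.,Loliginidae,pelagic squids
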