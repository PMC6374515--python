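((Mbrev,Srose)Choanoflagellida,(Aquee,(Mleid,(Tadha,(Nvect,(((Ctele,Acali)Lophotrochozoa,(Celeg,(Smari,Dmela)Arthropoda)Ecdysozoa)Protostomia,(Aplan,(Bbelc,Hsapi)Chordata)Deuterostomia)Bilateria)Planulozoa)Parahoxozoa)Eumetazoa)Metazoa)Choanozoa;
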