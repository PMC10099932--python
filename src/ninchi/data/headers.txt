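# Standard comment-header registry: Title:Description:Type1[;Type2;...]
Zpotential:Zeta potential value; units; URL to medium description:Float;Units;URI
Publication:Publication date; Authors; Journal name:Date;Text;Text
Taxonomy:Subphylum name; Link to taxonomy database:Enumeration(crustacean|fish|algae|rodent|human|bacteria);URI
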